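# VGG16 geometry (blocks 1-5, geometry only, no weights).  All convolutions
# are 3x3 stride 1 pad 1; pools are 2x2 stride 2.  Receptive fields grow
# slowly: 6 px at pool1, 16 px at pool2, 44 px at pool3.
layers:
  - {name: conv1_1, kind: conv, n_filters: 64, kernel_side: 3, stride: 1, pad: 1, n_input_channels: 3}
  - {name: relu1_1, kind: relu}
  - {name: conv1_2, kind: conv, n_filters: 64, kernel_side: 3, stride: 1, pad: 1, n_input_channels: 64}
  - {name: relu1_2, kind: relu}
  - {name: pool1, kind: maxpool, window: 2, stride: 2}
  - {name: conv2_1, kind: conv, n_filters: 128, kernel_side: 3, stride: 1, pad: 1, n_input_channels: 64}
  - {name: relu2_1, kind: relu}
  - {name: conv2_2, kind: conv, n_filters: 128, kernel_side: 3, stride: 1, pad: 1, n_input_channels: 128}
  - {name: relu2_2, kind: relu}
  - {name: pool2, kind: maxpool, window: 2, stride: 2}
  - {name: conv3_1, kind: conv, n_filters: 256, kernel_side: 3, stride: 1, pad: 1, n_input_channels: 128}
  - {name: relu3_1, kind: relu}
  - {name: conv3_2, kind: conv, n_filters: 256, kernel_side: 3, stride: 1, pad: 1, n_input_channels: 256}
  - {name: relu3_2, kind: relu}
  - {name: conv3_3, kind: conv, n_filters: 256, kernel_side: 3, stride: 1, pad: 1, n_input_channels: 256}
  - {name: relu3_3, kind: relu}
  - {name: pool3, kind: maxpool, window: 2, stride: 2}
  - {name: conv4_1, kind: conv, n_filters: 512, kernel_side: 3, stride: 1, pad: 1, n_input_channels: 256}
  - {name: relu4_1, kind: relu}
  - {name: conv4_2, kind: conv, n_filters: 512, kernel_side: 3, stride: 1, pad: 1, n_input_channels: 512}
  - {name: relu4_2, kind: relu}
  - {name: conv4_3, kind: conv, n_filters: 512, kernel_side: 3, stride: 1, pad: 1, n_input_channels: 512}
  - {name: relu4_3, kind: relu}
  - {name: pool4, kind: maxpool, window: 2, stride: 2}
  - {name: conv5_1, kind: conv, n_filters: 512, kernel_side: 3, stride: 1, pad: 1, n_input_channels: 512}
  - {name: relu5_1, kind: relu}
  - {name: conv5_2, kind: conv, n_filters: 512, kernel_side: 3, stride: 1, pad: 1, n_input_channels: 512}
  - {name: relu5_2, kind: relu}
  - {name: conv5_3, kind: conv, n_filters: 512, kernel_side: 3, stride: 1, pad: 1, n_input_channels: 512}
  - {name: relu5_3, kind: relu}
  - {name: pool5, kind: maxpool, window: 2, stride: 2}
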