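# Standard AlexNet/CaffeNet front end (conv1 stride 4); the L2 receptive
# field is 67 px instead of 39 px in the stride-2 variant.
layers:
  - {name: conv1, kind: conv, n_filters: 96, kernel_side: 11, stride: 4, pad: 0, n_input_channels: 3}
  - {name: relu1, kind: relu}
  - {name: pool1, kind: maxpool, window: 3, stride: 2}
  - {name: norm1, kind: lrn, k: 2.0, alpha: 1.0e-4, beta: 0.75, m: 5}
  - {name: conv2, kind: conv, n_filters: 256, kernel_side: 5, stride: 1, pad: 2, n_input_channels: 96}
  - {name: relu2, kind: relu}
  - {name: pool2, kind: maxpool, window: 3, stride: 2}
  - {name: norm2, kind: lrn, k: 2.0, alpha: 1.0e-4, beta: 0.75, m: 5}
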