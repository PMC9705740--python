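layers:
- kind: conv
  name: conv1
  kernel_h: 11
  kernel_w: 11
  filters: 64
  stride: 1
  padding: same
  rate: 0.5
- kind: activation
  name: act1
  kernel_h: 1
  kernel_w: 1
  filters: 1
  stride: 1
  padding: same
  rate: 0.5
- kind: maxpool
  name: pool1
  kernel_h: 3
  kernel_w: 3
  filters: 1
  stride: 2
  padding: same
  rate: 0.5
- kind: norm
  name: norm1
  kernel_h: 1
  kernel_w: 1
  filters: 1
  stride: 1
  padding: same
  rate: 0.5
- kind: conv
  name: conv2
  kernel_h: 5
  kernel_w: 5
  filters: 256
  stride: 1
  padding: same
  rate: 0.5
- kind: activation
  name: act2
  kernel_h: 1
  kernel_w: 1
  filters: 1
  stride: 1
  padding: same
  rate: 0.5
- kind: maxpool
  name: pool2
  kernel_h: 3
  kernel_w: 3
  filters: 1
  stride: 2
  padding: same
  rate: 0.5
- kind: norm
  name: norm2
  kernel_h: 1
  kernel_w: 1
  filters: 1
  stride: 1
  padding: same
  rate: 0.5
- kind: conv
  name: conv3
  kernel_h: 3
  kernel_w: 3
  filters: 256
  stride: 1
  padding: same
  rate: 0.5
- kind: activation
  name: act3
  kernel_h: 1
  kernel_w: 1
  filters: 1
  stride: 1
  padding: same
  rate: 0.5
- kind: conv
  name: conv4
  kernel_h: 3
  kernel_w: 3
  filters: 256
  stride: 1
  padding: same
  rate: 0.5
- kind: activation
  name: act4
  kernel_h: 1
  kernel_w: 1
  filters: 1
  stride: 1
  padding: same
  rate: 0.5
- kind: conv
  name: conv5
  kernel_h: 6
  kernel_w: 6
  filters: 4096
  stride: 1
  padding: same
  rate: 0.5
- kind: activation
  name: act5
  kernel_h: 1
  kernel_w: 1
  filters: 1
  stride: 1
  padding: same
  rate: 0.5
- kind: maxpool
  name: pool3
  kernel_h: 2
  kernel_w: 2
  filters: 1
  stride: 2
  padding: same
  rate: 0.5
- kind: conv
  name: conv6
  kernel_h: 6
  kernel_w: 6
  filters: 4096
  stride: 1
  padding: same
  rate: 0.5
- kind: activation
  name: act6
  kernel_h: 1
  kernel_w: 1
  filters: 1
  stride: 1
  padding: same
  rate: 0.5
- kind: maxpool
  name: pool4
  kernel_h: 2
  kernel_w: 2
  filters: 1
  stride: 2
  padding: same
  rate: 0.5
- kind: gap
  name: gap
  kernel_h: 1
  kernel_w: 1
  filters: 1
  stride: 1
  padding: same
  rate: 0.5
- kind: dense
  name: fc1
  kernel_h: 1
  kernel_w: 1
  filters: 4096
  stride: 1
  padding: same
  rate: 0.5
- kind: activation
  name: act7
  kernel_h: 1
  kernel_w: 1
  filters: 1
  stride: 1
  padding: same
  rate: 0.5
- kind: dropout
  name: drop1
  kernel_h: 1
  kernel_w: 1
  filters: 1
  stride: 1
  padding: same
  rate: 0.5
- kind: dense
  name: fc2
  kernel_h: 1
  kernel_w: 1
  filters: 3
  stride: 1
  padding: same
  rate: 0.5
- kind: softmax
  name: softmax
  kernel_h: 1
  kernel_w: 1
  filters: 1
  stride: 1
  padding: same
  rate: 0.5
input_shape:
- 224
- 224
- 3
class_count: 3
activation: nnlu
alpha: 0.333
lrn_radius: 2
lrn_k0: 2.0
lrn_a: 0.0001
lrn_b: 0.75
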