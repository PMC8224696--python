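{
 "total_parameters": 399556,
 "layers": [
  {
   "name": "stem.conv1.weight",
   "shape": [
    8,
    5
   ],
   "params": 40
  },
  {
   "name": "stem.bn1.gamma",
   "shape": [
    8
   ],
   "params": 8
  },
  {
   "name": "stem.bn1.beta",
   "shape": [
    8
   ],
   "params": 8
  },
  {
   "name": "stem.bn1.theta",
   "shape": [
    8
   ],
   "params": 8
  },
  {
   "name": "stem.conv2.weight",
   "shape": [
    32,
    40
   ],
   "params": 1280
  },
  {
   "name": "stem.bn2.gamma",
   "shape": [
    32
   ],
   "params": 32
  },
  {
   "name": "stem.bn2.beta",
   "shape": [
    32
   ],
   "params": 32
  },
  {
   "name": "stem.bn2.theta",
   "shape": [
    32
   ],
   "params": 32
  },
  {
   "name": "stem.conv3.weight",
   "shape": [
    32,
    160
   ],
   "params": 5120
  },
  {
   "name": "stem.bn3.gamma",
   "shape": [
    32
   ],
   "params": 32
  },
  {
   "name": "stem.bn3.beta",
   "shape": [
    32
   ],
   "params": 32
  },
  {
   "name": "stem.bn3.theta",
   "shape": [
    32
   ],
   "params": 32
  },
  {
   "name": "stage1.block1.conv1.weight",
   "shape": [
    32,
    160
   ],
   "params": 5120
  },
  {
   "name": "stage1.block1.bn1.gamma",
   "shape": [
    32
   ],
   "params": 32
  },
  {
   "name": "stage1.block1.bn1.beta",
   "shape": [
    32
   ],
   "params": 32
  },
  {
   "name": "stage1.block1.bn1.theta",
   "shape": [
    32
   ],
   "params": 32
  },
  {
   "name": "stage1.block1.conv2.weight",
   "shape": [
    32,
    160
   ],
   "params": 5120
  },
  {
   "name": "stage1.block1.bn2.gamma",
   "shape": [
    32
   ],
   "params": 32
  },
  {
   "name": "stage1.block1.bn2.beta",
   "shape": [
    32
   ],
   "params": 32
  },
  {
   "name": "stage1.block1.bn2.theta",
   "shape": [
    32
   ],
   "params": 32
  },
  {
   "name": "stage1.block2.conv1.weight",
   "shape": [
    32,
    160
   ],
   "params": 5120
  },
  {
   "name": "stage1.block2.bn1.gamma",
   "shape": [
    32
   ],
   "params": 32
  },
  {
   "name": "stage1.block2.bn1.beta",
   "shape": [
    32
   ],
   "params": 32
  },
  {
   "name": "stage1.block2.bn1.theta",
   "shape": [
    32
   ],
   "params": 32
  },
  {
   "name": "stage1.block2.conv2.weight",
   "shape": [
    32,
    160
   ],
   "params": 5120
  },
  {
   "name": "stage1.block2.bn2.gamma",
   "shape": [
    32
   ],
   "params": 32
  },
  {
   "name": "stage1.block2.bn2.beta",
   "shape": [
    32
   ],
   "params": 32
  },
  {
   "name": "stage1.block2.bn2.theta",
   "shape": [
    32
   ],
   "params": 32
  },
  {
   "name": "stage2.block1.conv1.weight",
   "shape": [
    64,
    160
   ],
   "params": 10240
  },
  {
   "name": "stage2.block1.bn1.gamma",
   "shape": [
    64
   ],
   "params": 64
  },
  {
   "name": "stage2.block1.bn1.beta",
   "shape": [
    64
   ],
   "params": 64
  },
  {
   "name": "stage2.block1.bn1.theta",
   "shape": [
    64
   ],
   "params": 64
  },
  {
   "name": "stage2.block1.conv2.weight",
   "shape": [
    64,
    320
   ],
   "params": 20480
  },
  {
   "name": "stage2.block1.bn2.gamma",
   "shape": [
    64
   ],
   "params": 64
  },
  {
   "name": "stage2.block1.bn2.beta",
   "shape": [
    64
   ],
   "params": 64
  },
  {
   "name": "stage2.block1.bn2.theta",
   "shape": [
    64
   ],
   "params": 64
  },
  {
   "name": "stage2.block1.short.conv.weight",
   "shape": [
    64,
    32
   ],
   "params": 2048
  },
  {
   "name": "stage2.block1.short.bn.gamma",
   "shape": [
    64
   ],
   "params": 64
  },
  {
   "name": "stage2.block1.short.bn.beta",
   "shape": [
    64
   ],
   "params": 64
  },
  {
   "name": "stage2.block1.short.bn.theta",
   "shape": [
    64
   ],
   "params": 64
  },
  {
   "name": "stage2.block2.conv1.weight",
   "shape": [
    64,
    320
   ],
   "params": 20480
  },
  {
   "name": "stage2.block2.bn1.gamma",
   "shape": [
    64
   ],
   "params": 64
  },
  {
   "name": "stage2.block2.bn1.beta",
   "shape": [
    64
   ],
   "params": 64
  },
  {
   "name": "stage2.block2.bn1.theta",
   "shape": [
    64
   ],
   "params": 64
  },
  {
   "name": "stage2.block2.conv2.weight",
   "shape": [
    64,
    320
   ],
   "params": 20480
  },
  {
   "name": "stage2.block2.bn2.gamma",
   "shape": [
    64
   ],
   "params": 64
  },
  {
   "name": "stage2.block2.bn2.beta",
   "shape": [
    64
   ],
   "params": 64
  },
  {
   "name": "stage2.block2.bn2.theta",
   "shape": [
    64
   ],
   "params": 64
  },
  {
   "name": "stage3.block1.conv1.weight",
   "shape": [
    128,
    320
   ],
   "params": 40960
  },
  {
   "name": "stage3.block1.bn1.gamma",
   "shape": [
    128
   ],
   "params": 128
  },
  {
   "name": "stage3.block1.bn1.beta",
   "shape": [
    128
   ],
   "params": 128
  },
  {
   "name": "stage3.block1.bn1.theta",
   "shape": [
    128
   ],
   "params": 128
  },
  {
   "name": "stage3.block1.conv2.weight",
   "shape": [
    128,
    640
   ],
   "params": 81920
  },
  {
   "name": "stage3.block1.bn2.gamma",
   "shape": [
    128
   ],
   "params": 128
  },
  {
   "name": "stage3.block1.bn2.beta",
   "shape": [
    128
   ],
   "params": 128
  },
  {
   "name": "stage3.block1.bn2.theta",
   "shape": [
    128
   ],
   "params": 128
  },
  {
   "name": "stage3.block1.short.conv.weight",
   "shape": [
    128,
    64
   ],
   "params": 8192
  },
  {
   "name": "stage3.block1.short.bn.gamma",
   "shape": [
    128
   ],
   "params": 128
  },
  {
   "name": "stage3.block1.short.bn.beta",
   "shape": [
    128
   ],
   "params": 128
  },
  {
   "name": "stage3.block1.short.bn.theta",
   "shape": [
    128
   ],
   "params": 128
  },
  {
   "name": "stage3.block2.conv1.weight",
   "shape": [
    128,
    640
   ],
   "params": 81920
  },
  {
   "name": "stage3.block2.bn1.gamma",
   "shape": [
    128
   ],
   "params": 128
  },
  {
   "name": "stage3.block2.bn1.beta",
   "shape": [
    128
   ],
   "params": 128
  },
  {
   "name": "stage3.block2.bn1.theta",
   "shape": [
    128
   ],
   "params": 128
  },
  {
   "name": "stage3.block2.conv2.weight",
   "shape": [
    128,
    640
   ],
   "params": 81920
  },
  {
   "name": "stage3.block2.bn2.gamma",
   "shape": [
    128
   ],
   "params": 128
  },
  {
   "name": "stage3.block2.bn2.beta",
   "shape": [
    128
   ],
   "params": 128
  },
  {
   "name": "stage3.block2.bn2.theta",
   "shape": [
    128
   ],
   "params": 128
  },
  {
   "name": "head.dense.weight",
   "shape": [
    4,
    128
   ],
   "params": 512
  },
  {
   "name": "head.dense.bias",
   "shape": [
    4
   ],
   "params": 4
  }
 ]
}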