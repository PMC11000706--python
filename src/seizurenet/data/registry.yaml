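# Model registry: one entry per study x task.  The BiLSTM and BiGRU variants
# of each entry share identical hyperparameters.
#
# units: [conv_filters, rnn_units_per_direction] per Conv->Bi-RNN->AvgPool
# unit, in order.  kernel_size applies to every conv stage of the entry.
# dense: hidden fully connected widths before the softmax output.
# dropout: rate between consecutive units (null = no dropout layers).
# missing: published values absent from the source description; the listed
# field holds the documented fallback and the resolved config is flagged
# incomplete.

defaults:
  batch_size: 64
  learning_rate: 0.001
  folds: 5
  pool_size: 2
  kernel_size: 2

studies:
  1:
    filtered: false
    segment: full
    tasks:
      A-E:
        units: [[32, 16], [16, 8]]
        dense: [100]
        epochs: 50
        dropout: 0.1
        missing: [dropout]
      B-E:
        units: [[32, 32], [16, 16]]
        dense: [100, 50, 10]
        epochs: 100
        dropout: 0.1
        missing: [dropout]
      AB-CD-E:
        units: [[64, 8], [128, 4]]
        dense: [80, 40, 20]
        epochs: 150
        dropout: 0.1
        missing: [dropout]
      AB-C-D-E:
        units: [[128, 32], [64, 16], [32, 8]]
        dense: [32]
        epochs: 150
        dropout: 0.1
        missing: [dropout]
      A-B-C-D-E:
        units: [[128, 32], [64, 16], [32, 8]]
        dense: [100, 50, 25]
        epochs: 150
        dropout: 0.1
        missing: [dropout]
  2:
    filtered: true
    segment: full
    tasks:
      A-E:
        units: [[4, 4], [8, 8]]
        dense: [100]
        epochs: 50
        dropout: 0.1
      B-E:
        units: [[16, 16], [8, 8]]
        dense: [100]
        epochs: 100
        dropout: 0.1
      AB-CD-E:
        units: [[256, 128], [64, 64], [32, 32]]
        dense: [200]
        epochs: 150
        dropout: 0.1
      AB-C-D-E:
        units: [[64, 64], [32, 32], [16, 16]]
        kernel_size: 4
        dense: [100]
        epochs: 150
        dropout: 0.1
        missing: [dense]
      A-B-C-D-E:
        units: [[128, 64], [64, 32], [32, 16]]
        kernel_size: 4
        dense: [50]
        epochs: 150
        dropout: 0.1
  3:
    filtered: false
    segment: 2048
    tasks:
      A-E:
        units: [[256, 64], [64, 32], [32, 16]]
        dense: [200, 50]
        epochs: 150
        dropout: 0.1
      B-E:
        units: [[256, 64], [64, 32], [32, 16]]
        dense: [200, 50]
        epochs: 150
        dropout: 0.1
      AB-CD-E:
        units: [[32, 16], [16, 8], [8, 4]]
        dense: [100, 40]
        epochs: 150
        dropout: 0.1
      AB-C-D-E:
        units: [[256, 32], [128, 32], [64, 16], [32, 8]]
        dense: [200, 100]
        epochs: 150
        dropout: 0.1
      A-B-C-D-E:
        units: [[64, 128], [128, 64], [256, 32]]
        dense: [100]
        epochs: 150
        dropout: 0.1
        missing: [dense]
  4:
    filtered: true
    segment: 2048
    tasks:
      A-E:
        units: [[16, 8], [32, 16]]
        dense: [100, 50, 10]
        epochs: 150
        dropout: 0.1
        missing: [epochs]
      B-E:
        units: [[32, 32], [64, 64], [128, 128]]
        dense: [100, 50]
        epochs: 150
        dropout: 0.1
        missing: [epochs]
      AB-CD-E:
        units: [[150, 100], [120, 50], [100, 25]]
        dense: [100]
        epochs: 150
        dropout: 0.1
        missing: [epochs]
      AB-C-D-E:
        units: [[32, 64], [64, 32], [128, 16], [256, 8]]
        dense: [200]
        epochs: 150
        dropout: 0.1
        missing: [epochs]
      A-B-C-D-E:
        units: [[32, 16], [64, 32], [128, 64]]
        dense: [100]
        epochs: 150
        dropout: 0.1
        missing: [dense, epochs]
  5:
    filtered: false
    segment: 178
    tasks:
      A-E:
        units: [[128, 64], [64, 32], [16, 16]]
        dense: [100]
        epochs: 150
        dropout: 0.1
        missing: [dense, epochs]
      B-E:
        units: [[128, 64], [64, 32], [32, 16]]
        dense: [100]
        epochs: 150
        dropout: 0.1
        missing: [dense, epochs]
      AB-CD-E:
        units: [[64, 32], [32, 16]]
        dense: [100, 20]
        epochs: 150
        dropout: 0.1
        missing: [epochs]
      AB-C-D-E:
        units: [[128, 128], [64, 64]]
        kernel_size: 4
        dense: [100, 40]
        epochs: 150
        dropout: 0.1
        missing: [epochs]
      A-B-C-D-E:
        units: [[300, 300], [150, 150]]
        kernel_size: 8
        dense: [100]
        epochs: 150
        dropout: 0.2
        missing: [dense, epochs]
  6:
    filtered: true
    segment: 178
    tasks:
      A-E:
        units: [[16, 8]]
        dense: [100, 10]
        epochs: 50
        dropout: null
      B-E:
        units: [[32, 16]]
        dense: [100, 10]
        epochs: 50
        dropout: null
      AB-CD-E:
        units: [[16, 8], [32, 16], [64, 32]]
        dense: [100, 50, 20]
        epochs: 150
        dropout: 0.1
      AB-C-D-E:
        units: [[64, 64], [128, 128]]
        dense: [100]
        epochs: 100
        dropout: 0.25
        missing: [dense]
      A-B-C-D-E:
        units: [[256, 256], [128, 128]]
        dense: [100]
        epochs: 100
        dropout: 0.25
        missing: [dense]
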