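"""Shared independent oracles and published reference tables for the tests."""
import numpy as np

from seizurenet.evaluation import MetricSet


def brute_force_metrics(counts):
    """Metric oracle: expand the confusion table into (true, predicted)
    pairs and collapse one-vs-rest tables explicitly."""
    pairs = [(t, p) for t in range(counts.shape[0])
             for p in range(counts.shape[1])
             for _ in range(counts[t, p])]
    n = len(pairs)
    accuracy = sum(t == p for t, p in pairs) / n
    k = counts.shape[0]

    def ovr(c):
        tp = sum(1 for t, p in pairs if t == c and p == c)
        fn = sum(1 for t, p in pairs if t == c and p != c)
        fp = sum(1 for t, p in pairs if t != c and p == c)
        tn = n - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        return sens, spec, f1

    if k == 2:
        sens, spec, f1 = ovr(1)  # positive class = highest index
    else:
        per = [ovr(c) for c in range(k)]
        sens, spec, f1 = (np.mean([row[j] for row in per]) for j in range(3))
    return MetricSet(100 * accuracy, 100 * spec, 100 * sens, 100 * f1)


#: Published unit-stack sizes: (study, task) -> [conv_filters, rnn_units].
PUBLISHED_UNITS = {
    (1, "A-E"): [[32, 16], [16, 8]],
    (1, "B-E"): [[32, 32], [16, 16]],
    (1, "AB-CD-E"): [[64, 8], [128, 4]],
    (1, "AB-C-D-E"): [[128, 32], [64, 16], [32, 8]],
    (1, "A-B-C-D-E"): [[128, 32], [64, 16], [32, 8]],
    (2, "A-E"): [[4, 4], [8, 8]],
    (2, "B-E"): [[16, 16], [8, 8]],
    (2, "AB-CD-E"): [[256, 128], [64, 64], [32, 32]],
    (2, "AB-C-D-E"): [[64, 64], [32, 32], [16, 16]],
    (2, "A-B-C-D-E"): [[128, 64], [64, 32], [32, 16]],
    (3, "A-E"): [[256, 64], [64, 32], [32, 16]],
    (3, "B-E"): [[256, 64], [64, 32], [32, 16]],
    (3, "AB-CD-E"): [[32, 16], [16, 8], [8, 4]],
    (3, "AB-C-D-E"): [[256, 32], [128, 32], [64, 16], [32, 8]],
    (3, "A-B-C-D-E"): [[64, 128], [128, 64], [256, 32]],
    (4, "A-E"): [[16, 8], [32, 16]],
    (4, "B-E"): [[32, 32], [64, 64], [128, 128]],
    (4, "AB-CD-E"): [[150, 100], [120, 50], [100, 25]],
    (4, "AB-C-D-E"): [[32, 64], [64, 32], [128, 16], [256, 8]],
    (4, "A-B-C-D-E"): [[32, 16], [64, 32], [128, 64]],
    (5, "A-E"): [[128, 64], [64, 32], [16, 16]],
    (5, "B-E"): [[128, 64], [64, 32], [32, 16]],
    (5, "AB-CD-E"): [[64, 32], [32, 16]],
    (5, "AB-C-D-E"): [[128, 128], [64, 64]],
    (5, "A-B-C-D-E"): [[300, 300], [150, 150]],
    (6, "A-E"): [[16, 8]],
    (6, "B-E"): [[32, 16]],
    (6, "AB-CD-E"): [[16, 8], [32, 16], [64, 32]],
    (6, "AB-C-D-E"): [[64, 64], [128, 128]],
    (6, "A-B-C-D-E"): [[256, 256], [128, 128]],
}

#: Segment length each study feeds to its models.
INPUT_LENGTHS = {1: 4097, 2: 4097, 3: 2048, 4: 2048, 5: 178, 6: 178}
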