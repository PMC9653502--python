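"""Brute-force confusion-count metric oracles, independent of the package."""


def oracle_hamming(Y_true, Y_pred):
    n, l = Y_true.shape
    disagreements = 0
    for i in range(n):
        for j in range(l):
            if Y_true[i, j] != Y_pred[i, j]:
                disagreements += 1
    return disagreements / (n * l)


def oracle_balanced_accuracy(Y_true, Y_pred):
    scores = []
    for j in range(Y_true.shape[1]):
        tp = fp = tn = fn = 0
        for i in range(Y_true.shape[0]):
            t, p = Y_true[i, j], Y_pred[i, j]
            if t and p:
                tp += 1
            elif t and not p:
                fn += 1
            elif not t and p:
                fp += 1
            else:
                tn += 1
        if tp + fn == 0 or tn + fp == 0:
            continue
        scores.append((tp / (tp + fn) + tn / (tn + fp)) / 2)
    return sum(scores) / len(scores)


def oracle_recall(Y_true, Y_pred):
    scores = []
    for j in range(Y_true.shape[1]):
        tp = fn = 0
        for i in range(Y_true.shape[0]):
            if Y_true[i, j] and Y_pred[i, j]:
                tp += 1
            elif Y_true[i, j] and not Y_pred[i, j]:
                fn += 1
        if tp + fn:
            scores.append(tp / (tp + fn))
    return sum(scores) / len(scores)
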