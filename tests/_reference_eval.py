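"""Independent reference detection evaluator (loop-based, threshold-sweep).

This is a from-scratch formulation used only as a cross-check oracle: IoU is
recomputed inline, matching is greedy over confidence with its own loop
structure, and average precision is evaluated by literally searching, for
each of the 101 recall samples, the best precision among all confidence
prefixes that reach that recall.
"""

import numpy as np


def _iou(a, b):
    ix1, iy1 = max(a[0], b[0]), max(a[1], b[1])
    ix2, iy2 = min(a[2], b[2]), min(a[3], b[3])
    if ix2 <= ix1 or iy2 <= iy1:
        return 0.0
    inter = (ix2 - ix1) * (iy2 - iy1)
    ar_a = (a[2] - a[0]) * (a[3] - a[1])
    ar_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (ar_a + ar_b - inter)


def _match_one_image(dets, gts, thr):
    """dets: [(conf, box)], gts: [box]; returns tp flags in given det order."""
    taken = set()
    flags = []
    for conf, box in dets:
        best_gi, best_v = None, thr
        for gi, gbox in enumerate(gts):
            if gi in taken:
                continue
            v = _iou(box, gbox)
            if v >= best_v:
                best_gi, best_v = gi, v
        if best_gi is None:
            flags.append(False)
        else:
            taken.add(best_gi)
            flags.append(True)
    return flags


def reference_ap(conf_flag_pairs, gt_count):
    """101-sample AP by explicit prefix search."""
    pairs = sorted(conf_flag_pairs, key=lambda t: -t[0])
    prefix = []
    tp = 0
    for i, (conf, flag) in enumerate(pairs):
        tp += int(flag)
        prefix.append((tp / gt_count, tp / (i + 1)))
    total = 0.0
    for s in range(101):
        target = s / 100.0
        best = 0.0
        for recall, precision in prefix:
            if recall >= target and precision > best:
                best = precision
        total += best
    return total / 101.0


def reference_map_suite(dets_by_image, gts_by_image, thresholds):
    """Returns (mAP at thresholds[0] == 0.5 expected, mean over thresholds)."""
    classes = sorted({g.class_id for gs in gts_by_image.values() for g in gs})
    gt_count = {
        c: sum(1 for gs in gts_by_image.values() for g in gs if g.class_id == c)
        for c in classes
    }
    per_thr_means = []
    for thr in thresholds:
        aps = []
        for c in classes:
            if gt_count[c] == 0:
                continue
            pairs = []
            for img, gts in gts_by_image.items():
                dets = sorted(
                    [(d.confidence, d.box) for d in dets_by_image.get(img, [])
                     if d.class_id == c],
                    key=lambda t: -t[0],
                )
                gboxes = [g.box for g in gts if g.class_id == c]
                flags = _match_one_image(dets, gboxes, thr)
                pairs.extend(zip([d[0] for d in dets], flags))
            aps.append(reference_ap(pairs, gt_count[c]))
        per_thr_means.append(float(np.mean(aps)) if aps else 0.0)
    return per_thr_means[0], float(np.mean(per_thr_means))
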