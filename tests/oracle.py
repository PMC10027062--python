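"""Brute-force recomputation of the QC quantities from their definitions.

Pure-Python loops, kept deliberately independent of the package's vectorised
implementation so the two can be compared as implementation vs oracle.
"""

import math


def oracle_qc(matrix, controls, thresholds, one_sided_band=False):
    """Recompute every per-sample QC quantity from first principles.

    Returns a list of dicts with the same fields as SampleQCRecord plus the
    run-level delta SD.
    """
    probes = list(matrix.probe_ids)
    samples = list(matrix.sample_ids)
    counts = [[int(matrix.counts[i][j]) for j in range(len(samples))] for i in range(len(probes))]
    n = len(samples)

    lib = [sum(counts[i][j] for i in range(len(probes))) for j in range(n)]
    cpm = [
        [counts[i][j] / lib[j] * 1e6 for j in range(n)] for i in range(len(probes))
    ]
    pos_rows = [probes.index(p) for p in sorted(controls.positive_ids)]
    neg_rows = [probes.index(p) for p in sorted(controls.negative_ids)]

    pos_pct = [100.0 * sum(counts[i][j] for i in pos_rows) / lib[j] for j in range(n)]
    neg_pct = [100.0 * sum(counts[i][j] for i in neg_rows) / lib[j] for j in range(n)]
    neg_mean = [sum(cpm[i][j] for i in neg_rows) / len(neg_rows) for j in range(n)]
    grand = sum(neg_mean) / n
    delta = [v - grand for v in neg_mean]
    if n >= 2:
        dm = sum(delta) / n
        sd = math.sqrt(sum((d - dm) ** 2 for d in delta) / (n - 1))
    else:
        sd = 0.0
    applied = n >= 3

    records = []
    for j in range(n):
        if pos_pct[j] > thresholds.pos_fail_pct:
            pflag = "FAIL"
        elif pos_pct[j] > thresholds.pos_alert_pct:
            pflag = "ALERT"
        else:
            pflag = "PASS"
        if neg_pct[j] > thresholds.neg_fail_pct:
            nflag = "FAIL"
        else:
            band = thresholds.sd_multiplier * sd
            outlier = delta[j] > band if one_sided_band else abs(delta[j]) > band
            nflag = "ALERT" if (applied and outlier) else "PASS"
        order = {"PASS": 0, "ALERT": 1, "FAIL": 2}
        overall = pflag if order[pflag] >= order[nflag] else nflag
        records.append(
            {
                "sample_id": samples[j],
                "library_size": lib[j],
                "pos_pct": pos_pct[j],
                "neg_pct": neg_pct[j],
                "neg_mean_cpm": neg_mean[j],
                "delta": delta[j],
                "pos_flag": pflag,
                "neg_flag": nflag,
                "overall_flag": overall,
            }
        )
    return records, sd
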