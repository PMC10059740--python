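"""Brute-force segmentation oracle, independent of the package implementation.

Enumerates maximal above-threshold index runs by linear scan, merges
adjacent runs by repeated pairwise gap scanning, and filters by peak
range and strict duration.  Used to cross-check the production TTI path.
"""

from feverwatch.tti import TTIConfig


def oracle_detections(r1, sample_rate: float, config: TTIConfig):
    """Return (start_index, end_index, peak, duration_s) tuples."""
    runs = []
    cur = None
    for i, v in enumerate(r1):
        if v > config.t_lim:
            if cur is None:
                cur = [i, i + 1]
            else:
                cur[1] = i + 1
        elif cur is not None:
            runs.append(cur)
            cur = None
    if cur is not None:
        runs.append(cur)

    changed = True
    while changed:
        changed = False
        for j in range(len(runs) - 1):
            if (runs[j + 1][0] - runs[j][1]) / sample_rate <= config.merge_gap_s:
                runs[j] = [runs[j][0], runs[j + 1][1]]
                del runs[j + 1]
                changed = True
                break

    out = []
    for s, e in runs:
        peak = max(r1[s:e])  # max over the full merged span
        dur = (e - s) / sample_rate
        if config.t_min_limit <= peak <= config.t_max_limit and dur > config.min_duration_s:
            out.append((s, e, float(peak), dur))
    return out
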