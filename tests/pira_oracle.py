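"""Brute-force reference for roving-baseline confirmed-worsening detection.

Written directly from the clinical definitions, independently of the
package's single-pass scanner: for every score it re-derives the baseline
in effect by existential search over (improvement, confirmation) index
pairs using whole-slice max/min checks, then enumerates every candidate
(event, confirmation) pair and returns the earliest valid one. O(n^3); for
tests only.
"""

MONTH = 30.4375
YEAR = 365.25
FOLLOW = 6 * YEAR
IMPROVE_CONF = 3 * MONTH


def _threshold(b):
    if b == 0:
        return 1.5
    if b <= 5.5:
        return 1.0
    return 0.5


def oracle_detect(baseline_edss, baseline_t, scores):
    """Return (pira, event_t, confirmed_at_t, baseline_values).

    `scores` is an iterable of (t, edss) in any order; only scores strictly
    after the baseline time participate.
    """
    pts = sorted((t, e) for t, e in scores if t > baseline_t)
    n = len(pts)
    cur = baseline_edss
    history = [cur]
    for i in range(n):
        t_i, e_i = pts[i]
        if e_i <= cur - 0.5:
            # improvement candidate: earliest j such that t_j is >= 3 months
            # later and every score in (t_i, t_j] stays strictly below the
            # current baseline
            valid = [
                j
                for j in range(i + 1, n)
                if pts[j][0] >= t_i + IMPROVE_CONF
                and max(e for _, e in pts[i + 1 : j + 1]) < cur
            ]
            if valid:
                j = min(valid)
                cur = min(e for _, e in pts[i : j + 1])
                history.append(cur)
            continue  # a score at/below baseline cannot be a worsening event
        if MONTH < t_i <= FOLLOW:
            level = cur + _threshold(cur)
            if e_i >= level:
                conf = [
                    j
                    for j in range(i + 1, n)
                    if pts[j][0] >= t_i + YEAR
                    and min(e for _, e in pts[i + 1 : j + 1]) >= level
                ]
                if conf:
                    return True, t_i, pts[min(conf)][0], history
    return False, None, None, history
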