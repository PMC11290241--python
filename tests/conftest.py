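import math

import pytest

from rapidmeta import MetaAnalysisData, TrialRecord, TwoByTwo


def make_trial(ma_id, trial_id, a, n1, c, n0, registered=True, posted=True,
               comparison_index=0):
    return TrialRecord(
        ma_id=ma_id,
        trial_id=trial_id,
        comparison_index=comparison_index,
        events_trt=a,
        n_trt=n1,
        events_ctl=c,
        n_ctl=n0,
        registered=registered,
        results_posted=posted and registered,
    )


@pytest.fixture
def small_ma():
    """Six-trial meta-analysis, mixed registration, no degenerate tables."""
    rows = [
        ("T1", 4, 100, 2, 100, True, True),
        ("T2", 10, 200, 5, 200, True, True),
        ("T3", 1, 50, 3, 50, True, False),
        ("T4", 6, 150, 4, 150, False, False),
        ("T5", 2, 80, 1, 80, True, True),
        ("T6", 5, 120, 6, 120, True, True),
    ]
    trials = [
        make_trial("MA1", tid, a, n1, c, n0, reg, post)
        for tid, a, n1, c, n0, reg, post in rows
    ]
    return MetaAnalysisData(ma_id="MA1", trials=tuple(trials))


# ---------------------------------------------------------------------------
# Independent brute-force oracles (deliberately naive, loop-based arithmetic;
# they share no code with the package implementations they check).


def oracle_mh(tables):
    """Mantel-Haenszel OR and RBG variance by direct summation."""
    R = S = 0.0
    for t in tables:
        n = t.a + t.b + t.c + t.d
        R += t.a * t.d / n
        S += t.b * t.c / n
    log_or = math.log(R / S)
    term1 = term2 = term3 = 0.0
    for t in tables:
        n = t.a + t.b + t.c + t.d
        P = (t.a + t.d) / n
        Q = (t.b + t.c) / n
        Ri = t.a * t.d / n
        Si = t.b * t.c / n
        term1 += P * Ri
        term2 += P * Si + Q * Ri
        term3 += Q * Si
    var = term1 / (2 * R * R) + term2 / (2 * R * S) + term3 / (2 * S * S)
    return log_or, var


def oracle_study_log_or(t, cc=0.5):
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + cc, b + cc, c + cc, d + cc
    return math.log(a * d / (b * c)), 1 / a + 1 / b + 1 / c + 1 / d


def oracle_dl(tables, cc=0.5):
    """DerSimonian-Laird pooling by direct formula on two-stage log ORs."""
    ys, vs = [], []
    for t in tables:
        if (t.a == 0 and t.c == 0) or (t.b == 0 and t.d == 0):
            continue
        y, v = oracle_study_log_or(t, cc)
        ys.append(y)
        vs.append(v)
    k = len(ys)
    w = [1 / v for v in vs]
    sw = sum(w)
    ybar = sum(wi * yi for wi, yi in zip(w, ys)) / sw
    q = sum(wi * (yi - ybar) ** 2 for wi, yi in zip(w, ys))
    denom = sw - sum(wi * wi for wi in w) / sw
    tau2 = max(0.0, (q - (k - 1)) / denom) if k > 1 else 0.0
    ws = [1 / (v + tau2) for v in vs]
    pooled = sum(wi * yi for wi, yi in zip(ws, ys)) / sum(ws)
    se = math.sqrt(1 / sum(ws))
    return pooled, se, tau2, q


def oracle_peto(tables):
    """Peto pooled log OR by direct O/E/V sums."""
    s_oe = s_v = 0.0
    for t in tables:
        n = t.a + t.b + t.c + t.d
        e = (t.a + t.b) * (t.a + t.c) / n
        v = (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d) / (
            n * n * (n - 1)
        )
        if v == 0:
            continue
        s_oe += t.a - e
        s_v += v
    return s_oe / s_v, 1 / math.sqrt(s_v)


def oracle_q_i2(ys, vs):
    w = [1 / v for v in vs]
    ybar = sum(wi * yi for wi, yi in zip(w, ys)) / sum(w)
    q = sum(wi * (yi - ybar) ** 2 for wi, yi in zip(w, ys))
    k = len(ys)
    i2 = max(0.0, (q - (k - 1)) / q) * 100 if q > 0 else 0.0
    return q, i2


#: Hand-sized 2x2 table collections used throughout the oracle suites.
ORACLE_TABLE_SETS = [
    [(4, 96, 2, 98), (10, 190, 5, 195), (1, 49, 3, 47)],
    [(10, 90, 5, 95)],
    [(10, 90, 5, 95), (10, 90, 5, 95)],
    [(3, 97, 1, 99), (0, 50, 2, 48), (5, 145, 5, 145)],
    [(1, 99, 0, 100), (2, 98, 1, 99)],
    [(7, 193, 3, 197), (2, 48, 4, 46), (12, 188, 9, 191), (1, 79, 0, 80)],
    [(20, 180, 10, 190), (15, 185, 18, 182)],
    [(2, 38, 1, 39), (3, 37, 5, 35), (1, 39, 1, 39), (4, 36, 2, 38)],
    [(50, 450, 30, 470), (40, 460, 45, 455), (60, 440, 50, 450)],
    [(1, 199, 1, 199), (2, 198, 3, 197), (0, 200, 1, 199), (4, 196, 2, 198),
     (1, 99, 2, 98)],
    [(9, 91, 12, 88), (6, 94, 4, 96), (11, 89, 8, 92)],
    [(3, 297, 6, 294), (8, 292, 2, 298), (5, 295, 5, 295), (1, 299, 4, 296)],
]


def as_tables(cells):
    return [TwoByTwo(*row) for row in cells]
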