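"""Behavioral analysis of the three-phase avoidance-transfer task.

Covers: 30-s binning of instrumental attacks and the first-vs-last-bin paired-t learning
check; the shield-rating exclusion rule (correct minus incorrect rating must be positive
for both outcomes); per-stimulus transfer response rates normalized by presentations;
a three-way fully within-subject ANOVA (interval x stimulus x response) with
Greenhouse-Geisser-corrected degrees of freedom and generalized eta squared; and
Bonferroni-corrected pairwise paired-t probes.

The ANOVA is computed from orthonormal within-subject contrasts: for each effect the
per-subject cell means are projected onto the Kronecker product of centered orthonormal
bases (factors in the effect) and normalized unit vectors (factors collapsed).  This
yields the classical univariate F with its effect-specific error term, the
Greenhouse-Geisser epsilon from the contrast covariance, and exact sums of squares for
generalized eta squared (eta^2_g = SS_effect / (SS_effect + SS_subjects + sum of all
error SS), the recommended effect size for repeated-measures designs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BehaviorError",
    "DegenerateVarianceError",
    "RatingSet",
    "bin_attacks",
    "learning_test",
    "instrumental_exclusion",
    "transfer_rates",
    "rm_anova_3way",
    "pairwise_probes",
    "default_probe_family",
]

STIMULI = ("CS1", "CS2", "CS3", "CS4", "CS5")
INTERVALS = ("pre", "stim")
RESPONSES = ("R1", "R2")


class BehaviorError(ValueError):
    """Invalid behavioral-analysis input."""


class DegenerateVarianceError(BehaviorError):
    """Paired differences have zero variance but a nonzero mean."""


# ---------------------------------------------------------------------------------------
# Instrumental phase
# ---------------------------------------------------------------------------------------


def bin_attacks(attacks, session_length_s: float = 180.0, bin_s: float = 30.0) -> np.ndarray:
    """Count attack onsets in consecutive ``bin_s`` bins of the session.

    If the session length is not divisible by the bin width the trailing partial bin is
    dropped with a warning.  An attack at exactly the covered span's end is assigned to
    the last bin (the generator emits window-end onsets, so a fully unavoided session
    ends with an attack at t = session length).
    """
    attacks = np.asarray(attacks, dtype=float)
    n_bins = int(np.floor(session_length_s / bin_s))
    if n_bins < 1:
        raise BehaviorError("bin width exceeds the session length")
    span = n_bins * bin_s
    if span < session_length_s:
        warnings.warn(
            f"session length {session_length_s}s not divisible by {bin_s}s; "
            "trailing partial bin dropped",
            stacklevel=2,
        )
    if attacks.size == 0:
        return np.zeros(n_bins, dtype=int)
    counts, _ = np.histogram(attacks, bins=n_bins, range=(0.0, span))
    return counts.astype(int)


def _paired_t(a: np.ndarray, b: np.ndarray):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise BehaviorError("paired t requires two equal-length vectors, n >= 2")
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        raise DegenerateVarianceError(
            "paired differences are constant and nonzero; t is unbounded"
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def learning_test(first_bin, last_bin):
    """Paired t of first-bin vs last-bin attack counts across subjects.

    Returns ``(t, df, p)`` with the t computed on (first - last), so successful
    avoidance learning yields a positive t.
    """
    return _paired_t(first_bin, last_bin)


@dataclass(frozen=True)
class RatingSet:
    """Post-instrumental shield-effectiveness ratings (1-10) per response-outcome pair."""

    subject_id: str
    ratings: dict  # (response, outcome) -> int

    def __post_init__(self):
        required = [(r, o) for r in ("R1", "R2") for o in ("O1", "O2")]
        missing = [k for k in required if k not in self.ratings]
        if missing:
            raise BehaviorError(f"missing ratings for {missing}")
        for k, v in self.ratings.items():
            if not 1 <= v <= 10:
                raise BehaviorError(f"rating {k} = {v} outside 1-10")


def instrumental_exclusion(ratings: RatingSet):
    """Apply the learning-check exclusion rule.

    For each outcome the incorrect-response rating is subtracted from the
    correct-response rating (correct pairings: R1-O1, R2-O2); a subject is excluded iff
    either score is <= 0.  Returns ``(keep, scores)``.
    """
    correct = {"O1": "R1", "O2": "R2"}
    incorrect = {"O1": "R2", "O2": "R1"}
    scores = {
        o: ratings.ratings[(correct[o], o)] - ratings.ratings[(incorrect[o], o)]
        for o in ("O1", "O2")
    }
    keep = all(s > 0 for s in scores.values())
    return keep, scores


# ---------------------------------------------------------------------------------------
# Transfer phase
# ---------------------------------------------------------------------------------------


def transfer_rates(
    record: pd.DataFrame,
    schedule: pd.DataFrame,
    reps_per_cs: int = 12,
    subject_id: str = "sub-01",
) -> pd.DataFrame:
    """Mean responses per presentation for every (stimulus, interval, response) cell.

    Presses are assigned to the 4-s stimulus windows and to the fixation window
    immediately preceding each stimulus; presses during recharge screens are ignored.
    Counts are divided by ``reps_per_cs`` (the number of presentations per stimulus).
    """
    if reps_per_cs <= 0:
        raise BehaviorError("reps_per_cs must be positive")
    if len(schedule) == 0:
        raise BehaviorError("empty transfer schedule")
    run_end = float((schedule["onset"] + schedule["duration"]).max())
    times = record["timestamp"].to_numpy(dtype=float) if len(record) else np.empty(0)
    if times.size and (times.min() < 0 or times.max() > run_end):
        raise BehaviorError("press timestamps fall outside the run span")
    counts = {
        (s, i, r): 0 for s, i, r in product(STIMULI, INTERVALS, RESPONSES)
    }
    rows = schedule.reset_index(drop=True)
    for idx in range(len(rows)):
        tt = rows.loc[idx, "trial_type"]
        if tt not in STIMULI:
            continue
        stim_on = float(rows.loc[idx, "onset"])
        stim_off = stim_on + float(rows.loc[idx, "duration"])
        windows = {"stim": (stim_on, stim_off)}
        if idx > 0 and rows.loc[idx - 1, "trial_type"] == "fixation":
            pre_on = float(rows.loc[idx - 1, "onset"])
            windows["pre"] = (pre_on, pre_on + float(rows.loc[idx - 1, "duration"]))
        for interval, (lo, hi) in windows.items():
            for resp in RESPONSES:
                sel = (
                    (record["response"] == resp).to_numpy()
                    & (times >= lo)
                    & (times < hi)
                    if len(record)
                    else np.zeros(0, bool)
                )
                counts[(tt, interval, resp)] += int(np.sum(sel))
    out = pd.DataFrame(
        [
            {
                "subject": subject_id,
                "stimulus": s,
                "interval": i,
                "response": r,
                "rate": counts[(s, i, r)] / reps_per_cs,
            }
            for s, i, r in product(STIMULI, INTERVALS, RESPONSES)
        ]
    )
    return out


# ---------------------------------------------------------------------------------------
# Three-way repeated-measures ANOVA
# ---------------------------------------------------------------------------------------

_FACTORS = (("stimulus", STIMULI), ("interval", INTERVALS), ("response", RESPONSES))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k matrix with orthonormal rows spanning the centered space."""
    c = np.eye(k) - np.ones((k, k)) / k
    u, s, vt = np.linalg.svd(c)
    return vt[: k - 1]


def _cell_array(table: pd.DataFrame) -> tuple[np.ndarray, list]:
    required = {"subject", "stimulus", "interval", "response", "rate"}
    missing = required - set(table.columns)
    if missing:
        raise BehaviorError(f"rate table missing columns {sorted(missing)}")
    subjects = sorted(table["subject"].unique())
    if len(subjects) < 2:
        raise BehaviorError("at least 2 subjects are required")
    lookup = {
        (row.subject, row.stimulus, row.interval, row.response): row.rate
        for row in table.itertuples(index=False)
    }
    missing_cells = [
        (sub, s, i, r)
        for sub in subjects
        for s, i, r in product(STIMULI, INTERVALS, RESPONSES)
        if (sub, s, i, r) not in lookup
    ]
    if missing_cells:
        raise BehaviorError(f"incomplete design; missing cells: {missing_cells[:5]}...")
    y = np.array(
        [
            [
                [[lookup[(sub, s, i, r)] for r in RESPONSES] for i in INTERVALS]
                for s in STIMULI
            ]
            for sub in subjects
        ],
        dtype=float,
    )
    return y, subjects


def rm_anova_3way(table: pd.DataFrame) -> pd.DataFrame:
    """Fully within-subject three-way ANOVA of the transfer rate table.

    Returns one row per effect (3 main effects, 3 two-way and 1 three-way interaction)
    with the classical F, uncorrected and Greenhouse-Geisser-corrected degrees of
    freedom, epsilon, the corrected p value, and generalized eta squared.
    """
    y, subjects = _cell_array(table)
    n = y.shape[0]
    flat = y.reshape(n, -1)  # stimulus-major ordering matches the kron products below

    bases = {name: _orthonormal_contrasts(len(levels)) for name, levels in _FACTORS}
    unit = {name: np.ones((1, len(levels))) / np.sqrt(len(levels)) for name, levels in _FACTORS}

    # subject sum of squares via the grand (all-collapsed) contrast
    grand = flat @ np.kron(np.kron(unit["stimulus"], unit["interval"]), unit["response"]).T
    ss_sub = float(np.sum((grand - grand.mean()) ** 2))

    effects = []
    for r in (1, 2, 3):
        for combo in _combinations_ordered(r):
            effects.append(combo)

    per_effect = {}
    total_err = 0.0
    for combo in effects:
        mats = [
            bases[name] if name in combo else unit[name] for name, _ in _FACTORS
        ]
        m = np.kron(np.kron(mats[0], mats[1]), mats[2])
        scores = flat @ m.T  # n x df1
        df1 = scores.shape[1]
        mean = scores.mean(axis=0)
        ss_eff = float(n * np.sum(mean**2))
        resid = scores - mean
        ss_err = float(np.sum(resid**2))
        total_err += ss_err
        per_effect[combo] = (scores, df1, ss_eff, ss_err)

    tol = 1e-10 * (1.0 + float(np.abs(flat).max())) ** 2
    rows = []
    for combo in effects:
        scores, df1, ss_eff, ss_err = per_effect[combo]
        ss_eff = 0.0 if ss_eff <= tol else ss_eff
        ss_err = 0.0 if ss_err <= tol else ss_err
        df2 = df1 * (n - 1)
        if ss_err == 0:
            f = 0.0 if ss_eff == 0 else np.inf
        else:
            f = (ss_eff / df1) / (ss_err / df2)
        if df1 == 1:
            eps = 1.0
        else:
            s_cov = np.cov(scores, rowvar=False, ddof=1)
            tr = np.trace(s_cov)
            tr2 = np.trace(s_cov @ s_cov)
            eps = 1.0 if tr2 == 0 else float(tr**2 / (df1 * tr2))
            eps = min(1.0, max(eps, 1.0 / df1))
        df1c, df2c = eps * df1, eps * df2
        if np.isinf(f):
            p = 0.0
        elif f == 0 and ss_eff == 0 and ss_err == 0:
            p = 1.0
        else:
            p = float(stats.f.sf(f, df1c, df2c))
        ges = 0.0 if ss_eff == 0 else ss_eff / (ss_eff + ss_sub + total_err)
        rows.append(
            {
                "effect": " x ".join(combo),
                "F": float(f),
                "df1": df1,
                "df2": df2,
                "eps": eps,
                "df1_corr": df1c,
                "df2_corr": df2c,
                "p": p,
                "ges": float(ges),
            }
        )
    return pd.DataFrame(rows)


def _combinations_ordered(r: int):
    from itertools import combinations

    names = [name for name, _ in _FACTORS]
    return [combo for combo in combinations(names, r)]


# ---------------------------------------------------------------------------------------
# Pairwise probes
# ---------------------------------------------------------------------------------------


def default_probe_family() -> list[dict]:
    """Per conditioned stimulus, the four contrasts probing interval and response:
    R1 pre-vs-stim, R2 pre-vs-stim, R1-vs-R2 within pre, R1-vs-R2 within stim
    (20 comparisons total, corrected as one family)."""
    family = []
    for s in STIMULI:
        for r in RESPONSES:
            family.append(
                {
                    "name": f"{s}:{r}:pre-vs-stim",
                    "cell_a": {"stimulus": s, "interval": "stim", "response": r},
                    "cell_b": {"stimulus": s, "interval": "pre", "response": r},
                }
            )
        for i in INTERVALS:
            family.append(
                {
                    "name": f"{s}:{i}:R1-vs-R2",
                    "cell_a": {"stimulus": s, "interval": i, "response": "R1"},
                    "cell_b": {"stimulus": s, "interval": i, "response": "R2"},
                }
            )
    return family


def _cell_values(table: pd.DataFrame, cell: dict, subjects) -> np.ndarray:
    sel = table
    for k, v in cell.items():
        sel = sel[sel[k] == v]
    vals = sel.set_index("subject")["rate"]
    try:
        return vals.loc[list(subjects)].to_numpy(dtype=float)
    except KeyError as err:
        raise BehaviorError(f"cell {cell} missing for some subjects") from err


def pairwise_probes(
    table: pd.DataFrame,
    family: list[dict] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired-t probes of within-subject cell contrasts with Bonferroni correction.

    Each family entry names two cells of the (stimulus, interval, response) design; the
    adjusted p is min(1, raw p x family size).  Returns a tidy frame with raw and
    adjusted p values and significance flags at ``alpha``.
    """
    if family is None:
        family = default_probe_family()
    keys = [
        (tuple(sorted(c["cell_a"].items())), tuple(sorted(c["cell_b"].items())))
        for c in family
    ]
    if len(set(keys)) != len(keys):
        raise BehaviorError("duplicate comparisons in the probe family")
    subjects = sorted(table["subject"].unique())
    m = len(family)
    rows = []
    for comp in family:
        a = _cell_values(table, comp["cell_a"], subjects)
        b = _cell_values(table, comp["cell_b"], subjects)
        t, df, p = _paired_t(a, b)
        p_adj = min(1.0, p * m)
        rows.append(
            {
                "comparison": comp["name"],
                "t": t,
                "df": df,
                "p_raw": p,
                "p_bonferroni": p_adj,
                "significant": p_adj < alpha,
                "mean_diff": float(np.mean(a - b)),
            }
        )
    return pd.DataFrame(rows)
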