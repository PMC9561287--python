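"""Cohort-level translation statistics: survival, dwells, pathway maps.

Conventions follow the assay's accounting: the survival curve counts
translating ribosomes (at least one decoded codon), so censored traces
contribute up to their last decoded codon; the pathway map conditions on
ribosomes that decoded the suppression codon and reports censored traces
as their own category; dwell means are exponential maximum-likelihood
estimates (the sample mean) over observed, uncensored dwells with
nonparametric bootstrap intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .detect import DISASSEMBLY_50S, DISASSEMBLY_70S, TraceOutcome

__all__ = [
    "SurvivalCurve",
    "PathwayMap",
    "DwellSummary",
    "survival_curve",
    "decoding_efficiency",
    "dwell_summary",
    "pathway_map",
    "compare_conditions",
]

SUP_CODON = 2  # suppression codon of the default reporter


@dataclass
class SurvivalCurve:
    """Codon survival: fraction of translating ribosomes reaching each codon."""

    condition: str
    n_total: int
    table: pd.DataFrame  # columns: codon, n_reaching, fraction, conditional_survival
    _outcomes: list[TraceOutcome] = field(default_factory=list, repr=False)

    def fraction(self, codon: int) -> float:
        return float(self.table.set_index("codon").loc[codon, "fraction"])

    def conditional_survival(self, codon: int) -> float:
        return float(self.table.set_index("codon").loc[codon, "conditional_survival"])


@dataclass
class PathwayMap:
    """Fate map of ribosomes that decoded the suppression codon."""

    condition: str
    n_decoders: int
    counts: dict[str, int]
    fractions: dict[str, float]
    mode_split: dict[str, float]  # 50S vs 70S among disassembly events
    _outcomes: list[TraceOutcome] = field(default_factory=list, repr=False)


@dataclass
class DwellSummary:
    """Exponential MLE of one dwell class with a bootstrap interval."""

    event_class: str
    codon: int | None
    n: int
    mle_mean: float
    ci_low: float
    ci_high: float
    dwells: np.ndarray = field(default=None, repr=False)


def _qualifying(outcomes: list[TraceOutcome]) -> list[TraceOutcome]:
    """Translating ribosomes: traces with at least one decoded codon."""
    return [o for o in outcomes if o.decoded_codons >= 1]


def survival_curve(
    outcomes: list[TraceOutcome], n_codons: int = 6, condition: str = ""
) -> SurvivalCurve:
    """Codon survival plot data.

    ``fraction(k)`` is the share of translating ribosomes whose decoded
    codon count reaches ``k``; censored traces count toward every codon
    they decoded.  Fractions are nonincreasing and ``fraction(1) = 1`` by
    construction.
    """
    qual = _qualifying(outcomes)
    if not qual:
        raise ValueError("no traces decoded any codon; cannot build a survival curve")
    decoded = np.array([o.decoded_codons for o in qual])
    rows = []
    prev_frac = None
    for k in range(1, n_codons + 1):
        n_reach = int((decoded >= k).sum())
        frac = n_reach / len(qual)
        cond = 1.0 if prev_frac in (None, 0.0) else frac / prev_frac
        rows.append(
            {"codon": k, "n_reaching": n_reach, "fraction": frac, "conditional_survival": cond}
        )
        prev_frac = frac
    return SurvivalCurve(
        condition=condition,
        n_total=len(qual),
        table=pd.DataFrame(rows),
        _outcomes=qual,
    )


def decoding_efficiency(
    outcomes: list[TraceOutcome], codon: int, n_codons: int = 6
) -> dict:
    """Fraction of ribosomes decoding ``codon`` among those decoding the one before.

    Returns the point estimate with a Wilson 95% interval.
    """
    if not 1 <= codon <= n_codons:
        raise ValueError(f"codon must be in 1..{n_codons}")
    if codon > 1:
        denom = [o for o in outcomes if o.decoded_codons >= codon - 1]
        if not denom:
            raise ValueError(f"no trace decoded codon {codon - 1}")
    else:
        denom = list(outcomes)
        if not denom:
            raise ValueError("empty cohort")
    k = sum(o.decoded_codons >= codon for o in denom)
    n = len(denom)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return {"codon": codon, "n": n, "k": k, "fraction": k / n, "ci95": (float(lo), float(hi))}


def _dwell_sample(
    outcomes: list[TraceOutcome], event_class: str, codon: int | None
) -> np.ndarray:
    if event_class == "decoding":
        vals = [o.decoding_dwells[codon] for o in outcomes if codon in o.decoding_dwells]
    elif event_class == "rotated":
        vals = [o.rotated_dwells[codon] for o in outcomes if codon in o.rotated_dwells]
    elif event_class == "disassembly":
        # dwell from the suppressor's translocation to the disassembly
        # signature: post-translocation events at the suppression codon
        sup = codon if codon is not None else SUP_CODON
        vals = [
            o.disassembly_dwell
            for o in outcomes
            if o.disassembly_dwell is not None
            and o.disassembly_phase == "post_translocation"
            and o.decoded_codons == sup
        ]
    else:
        raise ValueError(f"unknown dwell class {event_class!r}")
    return np.asarray(vals, dtype=float)


def dwell_summary(
    outcomes: list[TraceOutcome],
    event_class: str,
    codon: int | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> DwellSummary:
    """Exponential MLE of a dwell class with a bootstrap 95% interval.

    The MLE of an exponential mean is the arithmetic mean of the sample;
    censored dwells never enter (the classifier leaves them undefined).
    """
    dwells = _dwell_sample(outcomes, event_class, codon)
    if dwells.size == 0:
        raise ValueError(f"no observed dwells for class {event_class!r}")
    mean = float(dwells.mean())
    if dwells.size == 1:
        lo = hi = mean
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, dwells.size, size=(n_boot, dwells.size))
        boot = dwells[idx].mean(axis=1)
        lo, hi = (float(q) for q in np.percentile(boot, [2.5, 97.5]))
        lo, hi = min(lo, mean), max(hi, mean)
    return DwellSummary(
        event_class=event_class,
        codon=codon,
        n=int(dwells.size),
        mle_mean=mean,
        ci_low=lo,
        ci_high=hi,
        dwells=dwells,
    )


def _pathway_category(o: TraceOutcome, sup_codon: int = SUP_CODON) -> str:
    if o.decoded_codons > sup_codon:
        return "survived"
    if o.outcome in (DISASSEMBLY_50S, DISASSEMBLY_70S) and o.decoded_codons == sup_codon:
        if o.disassembly_phase == "pre_translocation":
            return "pre_dis"
        return "post_dis"
    return "censored"


def pathway_map(
    outcomes: list[TraceOutcome], condition: str = "", sup_codon: int = SUP_CODON
) -> PathwayMap:
    """Fates of ribosomes conditional on decoding the suppression codon.

    Categories: disassembly before the suppressor's translocation,
    disassembly after it, survival to the next codon, and censored
    (movie end, stall or signal loss before the fate resolved).
    Fractions are over all decoders and sum to 1.
    """
    decoders = [o for o in outcomes if o.decoded_codons >= sup_codon]
    if not decoders:
        raise ValueError("no trace decoded the suppression codon")
    counts = {"pre_dis": 0, "post_dis": 0, "survived": 0, "censored": 0}
    n50 = n70 = 0
    for o in decoders:
        counts[_pathway_category(o, sup_codon)] += 1
        if o.decoded_codons == sup_codon:
            if o.outcome == DISASSEMBLY_50S:
                n50 += 1
            elif o.outcome == DISASSEMBLY_70S:
                n70 += 1
    n = len(decoders)
    fractions = {k: v / n for k, v in counts.items()}
    n_dis = n50 + n70
    mode_split = {
        "50S": n50 / n_dis if n_dis else float("nan"),
        "70S": n70 / n_dis if n_dis else float("nan"),
    }
    return PathwayMap(
        condition=condition,
        n_decoders=n,
        counts=counts,
        fractions=fractions,
        mode_split=mode_split,
        _outcomes=decoders,
    )


def _fields_of(stat) -> dict[str, float]:
    if isinstance(stat, PathwayMap):
        return dict(stat.fractions)
    if isinstance(stat, SurvivalCurve):
        out = {}
        for _, row in stat.table.iterrows():
            k = int(row["codon"])
            out[f"fraction_codon{k}"] = float(row["fraction"])
            out[f"conditional_survival_codon{k}"] = float(row["conditional_survival"])
        return out
    raise TypeError("compare_conditions accepts PathwayMap or SurvivalCurve pairs")


def _rebuild(stat, outcomes):
    if isinstance(stat, PathwayMap):
        return pathway_map(outcomes, condition=stat.condition)
    return survival_curve(outcomes, n_codons=len(stat.table), condition=stat.condition)


def compare_conditions(a, b, n_boot: int = 1000, seed: int = 0) -> dict:
    """Fold change (a over b) per shared field, with bootstrap 95% CIs.

    Both statistics must be of the same type and carry their source
    outcomes; traces are resampled within each cohort and the statistic
    rebuilt per replicate (percentile intervals).  A zero denominator
    yields NaN for that field rather than an error.
    """
    if type(a) is not type(b):
        raise TypeError("can only compare statistics of the same type")
    fa, fb = _fields_of(a), _fields_of(b)
    shared = [k for k in fa if k in fb]

    def fold(x, y):
        return x / y if y else float("nan")

    point = {k: fold(fa[k], fb[k]) for k in shared}

    rng = np.random.default_rng(seed)
    oa, ob = a._outcomes, b._outcomes
    boots: dict[str, list[float]] = {k: [] for k in shared}
    for _ in range(n_boot):
        ra = [oa[i] for i in rng.integers(0, len(oa), len(oa))]
        rb = [ob[i] for i in rng.integers(0, len(ob), len(ob))]
        try:
            sa, sb = _rebuild(a, ra), _rebuild(b, rb)
        except ValueError:
            continue
        ga, gb = _fields_of(sa), _fields_of(sb)
        for k in shared:
            boots[k].append(fold(ga.get(k, float("nan")), gb.get(k, float("nan"))))
    report = {}
    for k in shared:
        arr = np.asarray(boots[k], dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size:
            lo, hi = np.percentile(arr, [2.5, 97.5])
        else:
            lo = hi = float("nan")
        report[k] = {"fold": point[k], "ci95": (float(lo), float(hi))}
    return report
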