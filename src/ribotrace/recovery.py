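"""Parameter-recovery suite: the printed kinetic quantities, end to end.

Each row of the suite simulates a cohort under a registered condition,
runs the full render -> detect -> classify -> summarize pipeline, and
compares the recovered statistic against the value implied by the preset
(closed-form branch products and dwell means).  Tolerances are
max(3 binomial SEs, 2 percentage points) for fractions (1 point for the
rare natural-suppressor disassembly branch), 1 s for dwell means and 0.3
for the concentration fold change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .emission import EmissionConfig
from .kinetics import expected_fractions, make_preset
from .pipeline import CohortResult, run_condition
from .stats import (
    compare_conditions,
    decoding_efficiency,
    dwell_summary,
    pathway_map,
    survival_curve,
)

__all__ = ["recovery_suite", "cohort_seeds"]


def cohort_seeds(seed: int, n: int = 8) -> list[int]:
    """Derive independent cohort seeds from one master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n)]


def _binom_tol(p_hat: float, n: int, floor: float = 0.02) -> float:
    se = np.sqrt(max(p_hat * (1.0 - p_hat), 1e-12) / max(n, 1))
    return max(3.0 * se, floor)


def recovery_suite(
    seed: int = 1,
    n: int = 2000,
    n_rare: int = 4000,
    emission_cfg: EmissionConfig | None = None,
) -> pd.DataFrame:
    """Run every recovery target and return a tidy pass/fail table.

    ``n`` traces are simulated per condition (``n_rare`` for the
    natural-suppressor cohort whose disassembly branch is ~1%).
    """
    seeds = cohort_seeds(seed)
    cfg = emission_cfg or EmissionConfig()

    ut50 = run_condition(make_preset("UTu1", 50, 1.0), n, seeds[0], cfg)
    ut200 = run_condition(make_preset("UTu1", 200, 1.0), n, seeds[1], cfg)
    supd = run_condition(make_preset("supD", 50, 1.0), n, seeds[2], cfg)
    supd_rare = run_condition(make_preset("supD", 50, 1.0), n_rare, seeds[3], cfg)
    ut1a = run_condition(make_preset("UTu1A", 50, 1.0), n, seeds[4], cfg)

    rows: list[dict] = []

    def add(statistic, condition, expected, measured, tol, n_used, unit):
        rows.append(
            {
                "statistic": statistic,
                "condition": condition,
                "expected": expected,
                "measured": measured,
                "tol": tol,
                "n": n_used,
                "unit": unit,
                "passed": bool(abs(measured - expected) <= tol),
            }
        )

    def add_decoding(cohort: CohortResult):
        eff = decoding_efficiency(cohort.outcomes, 2)
        add(
            "decoding_efficiency_codon2",
            cohort.preset.preset_id,
            cohort.preset.p_decode_sup,
            eff["fraction"],
            _binom_tol(eff["fraction"], eff["n"]),
            eff["n"],
            "fraction",
        )

    def add_survival(cohort: CohortResult):
        sc = survival_curve(cohort.outcomes, condition=cohort.preset.preset_id)
        meas = sc.conditional_survival(3)
        n_denom = int(sc.table.set_index("codon").loc[2, "n_reaching"])
        add(
            "conditional_survival_codon3",
            cohort.preset.preset_id,
            expected_fractions(cohort.preset)["p_survive_codon3_given_decode"],
            meas,
            _binom_tol(meas, n_denom),
            n_denom,
            "fraction",
        )

    def add_pathway(cohort: CohortResult, which: str, floor: float = 0.02):
        pm = pathway_map(cohort.outcomes, condition=cohort.preset.preset_id)
        key = "p_pre_dis_given_decode" if which == "pre_dis" else "p_post_dis_given_decode"
        meas = pm.fractions[which]
        add(
            f"pathway_{which}",
            cohort.preset.preset_id,
            expected_fractions(cohort.preset)[key],
            meas,
            _binom_tol(meas, pm.n_decoders, floor),
            pm.n_decoders,
            "fraction",
        )
        return pm

    add_decoding(ut50)
    add_decoding(supd)
    add_survival(ut50)
    add_survival(supd)
    pm50 = add_pathway(ut50, "pre_dis")
    add_pathway(ut50, "post_dis")
    add_pathway(supd_rare, "post_dis", floor=0.01)
    add_survival(ut200)
    add_survival(ut1a)

    dis = dwell_summary(ut50.outcomes, "disassembly", n_boot=500, seed=seeds[5])
    add(
        "disassembly_dwell_mean",
        ut50.preset.preset_id,
        ut50.preset.t_disassembly_mean,
        dis.mle_mean,
        1.0,
        dis.n,
        "s",
    )
    dec = dwell_summary(ut50.outcomes, "decoding", codon=2, n_boot=500, seed=seeds[6])
    add(
        "decoding_dwell_codon2_mean",
        ut50.preset.preset_id,
        ut50.preset.t_decode_sup_mean,
        dec.mle_mean,
        1.0,
        dec.n,
        "s",
    )

    pm200 = pathway_map(ut200.outcomes, condition=ut200.preset.preset_id)
    cmp_report = compare_conditions(pm50, pm200, n_boot=300, seed=seeds[7])
    exp_fold = (
        expected_fractions(ut50.preset)["p_post_dis_given_decode"]
        / expected_fractions(ut200.preset)["p_post_dis_given_decode"]
    )
    add(
        "post_dis_fold_50_over_200",
        "UTu1@50nM/UTu1@200nM",
        exp_fold,
        cmp_report["post_dis"]["fold"],
        0.3,
        min(pm50.n_decoders, pm200.n_decoders),
        "fold",
    )

    return pd.DataFrame(rows)
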