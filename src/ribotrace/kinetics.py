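"""Semi-Markov kinetic model of suppression-containing translation elongation.

The model describes a single ribosome translating a short mRNA in a
zero-mode-waveguide experiment.  A 30S pre-initiation complex sits in the
well from movie start; reagents (quencher-labelled 50S, dye-labelled
ternary complexes, suppressor ternary complex, EF-G) are delivered at
``DELIVERY_TIME``.  Elongation then proceeds through alternating
non-rotated / rotated intersubunit states, one cycle per codon.  At the
suppression codon the ribosome may fail to decode (stall), disassemble
from the rotated state before translocation, or — after translocating the
suppressor tRNA into the P site — continue, disassemble, or drop out of
observation.  Disassembly comes in two modes: loss of the 50S subunit
(the green dye dequenches) or loss of the whole 70S from the mRNA (the
green signal disappears).

Branching is parameterised directly by outcome probabilities, with an
independent exponential dwell per branch, rather than by competing rates:
the printed fractions of the experiment are then preset parameters and
parameter recovery by the analysis pipeline is unambiguous.

Dwells are drawn as shifted exponentials: a short refractory floor
(``dwell_floor``, default 0.5 s) plus an exponential chosen so the total
mean equals the preset mean.  Conformational transitions are not
instantaneous, and a pure exponential would put a sizeable mass of dwells
below any finite detector dead time, making the printed branch fractions
unrecoverable from rendered traces by construction rather than by noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DELIVERY_TIME",
    "MOVIE_LENGTH",
    "CodonSlot",
    "CodonProgram",
    "default_program",
    "PostBranch",
    "KineticPreset",
    "PRESET_NAMES",
    "make_preset",
    "expected_fractions",
    "Interval",
    "Trajectory",
    "sample_trajectory",
]

#: time (s) at which the delivery mixture reaches the well
DELIVERY_TIME = 10.0
#: movie length (s); all trajectories are right-censored here
MOVIE_LENGTH = 360.0

# interval state labels
PIC = "PIC"
NONROT = "NONROT"
ROT = "ROT"
DIS_50S = "DISASSEMBLED_50S"
DIS_70S = "DISASSEMBLED_70S"
STALLED = "STALLED"
BLEACHED = "BLEACHED"

TERMINAL_STATES = frozenset({DIS_50S, DIS_70S, STALLED, BLEACHED})


@dataclass(frozen=True)
class CodonSlot:
    """One elongation codon: which tRNA decodes it and whether that tRNA is dye-labelled."""

    index: int
    trna: str
    dye_labeled: bool


@dataclass(frozen=True)
class CodonProgram:
    """Ordered elongation codons after the initiator.

    Exactly one slot must carry the suppressor species ``"Sup"``; slot
    indices are consecutive from 1.
    """

    slots: tuple[CodonSlot, ...]

    def __post_init__(self) -> None:
        if not self.slots:
            raise ValueError("codon program must contain at least one slot")
        for i, slot in enumerate(self.slots, start=1):
            if slot.index != i:
                raise ValueError("codon indices must be consecutive from 1")
        n_sup = sum(s.trna == "Sup" for s in self.slots)
        if n_sup != 1:
            raise ValueError("codon program must contain exactly one suppression slot")

    def __len__(self) -> int:
        return len(self.slots)

    def __getitem__(self, i: int) -> CodonSlot:
        return self.slots[i]

    @property
    def sup_index(self) -> int:
        return next(s.index for s in self.slots if s.trna == "Sup")


def default_program() -> CodonProgram:
    """Six-codon reporter: Phe, UAG(sup), Phe, Phe, Phe, Phe.

    Codon 2 is the suppressed stop codon (unlabelled suppressor tRNA);
    all other codons are read by dye-labelled tRNA(Phe), so the first and
    last four cycles carry red-channel occupancy signals.
    """
    slots = []
    for i in range(1, 7):
        if i == 2:
            slots.append(CodonSlot(i, "Sup", False))
        else:
            slots.append(CodonSlot(i, "Phe", True))
    return CodonProgram(tuple(slots))


@dataclass(frozen=True)
class PostBranch:
    """Branch probabilities after suppressor translocation into the P site."""

    continue_: float
    disassemble: float
    censor: float

    def as_dict(self) -> dict:
        return {
            "continue": self.continue_,
            "disassemble": self.disassemble,
            "censor": self.censor,
        }


@dataclass(frozen=True)
class KineticPreset:
    """All branch probabilities and dwell-time means for one condition.

    Dwells are means of exponential distributions, in seconds.  Branch
    probabilities are conditional: ``p_pre_dis`` on decoding the
    suppression codon, ``p_post`` on surviving to translocation.
    """

    preset_id: str
    name: str
    tc_phe_conc: float  # nM
    sup_tc_conc: float  # uM
    t_join_mean: float
    t_arrival_mean: float
    t_accom_mean: float
    t_decode_sup_mean: float
    t_rotated_mean: float
    t_disassembly_mean: float
    p_decode_sup: float
    p_pre_dis: float
    p_post: PostBranch
    p_continue_late: float
    p_mode_50S: float
    bleach_rate_green: float
    bleach_rate_red: float
    dwell_floor: float = 0.5

    def __post_init__(self) -> None:
        for label in ("p_decode_sup", "p_pre_dis", "p_continue_late", "p_mode_50S"):
            v = getattr(self, label)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{label} must be in [0, 1], got {v}")
        for label in (
            "t_join_mean",
            "t_arrival_mean",
            "t_accom_mean",
            "t_decode_sup_mean",
            "t_rotated_mean",
            "t_disassembly_mean",
        ):
            if getattr(self, label) <= 0:
                raise ValueError(f"{label} must be positive")
        p = self.p_post
        for v in (p.continue_, p.disassemble, p.censor):
            if not 0.0 <= v <= 1.0:
                raise ValueError("post-translocation branch probabilities must be in [0, 1]")
        if abs(p.continue_ + p.disassemble + p.censor - 1.0) > 1e-9:
            raise ValueError("post-translocation branch probabilities must sum to 1")
        if self.bleach_rate_green < 0 or self.bleach_rate_red < 0:
            raise ValueError("bleach rates must be nonnegative")


# Registered conditions.  Branch probabilities at the reference 50 nM
# dye-TC concentration, with explicit overrides where a condition was
# measured at another concentration.  The post-translocation triple for
# the allo-tRNA at 50 nM solves 0.91*x = {0.21, 0.64} for the continue and
# disassemble branches, with the residual as the censored branch.
_REGISTRY: dict[str, dict] = {
    "UTu1": dict(
        p_decode_sup=0.83,
        p_pre_dis=0.09,
        p_post=PostBranch(0.2308, 0.7033, 0.0659),
        t_decode_sup_1uM=7.0,
        overrides={
            200.0: dict(p_pre_dis=0.0, p_post=PostBranch(0.72, 0.256, 0.024)),
        },
    ),
    "supD": dict(
        p_decode_sup=0.72,
        p_pre_dis=0.0,
        p_post=PostBranch(0.84, 0.01, 0.15),
        t_decode_sup_1uM=7.0,
        overrides={},
    ),
    "UTu1A": dict(
        p_decode_sup=0.83,
        p_pre_dis=0.0,
        p_post=PostBranch(0.75, 0.19, 0.06),
        t_decode_sup_1uM=7.0,
        overrides={},
    ),
    "Ser": dict(
        p_decode_sup=0.95,
        p_pre_dis=0.0,
        p_post=PostBranch(0.92, 0.01, 0.07),
        t_decode_sup_1uM=3.5,
        overrides={},
    ),
}

PRESET_NAMES = tuple(_REGISTRY)

# dwell means (s) shared across conditions
_T_JOIN_MEAN = 5.0
_T_ROTATED_MEAN = 2.0
_T_DISASSEMBLY_MEAN = 9.0
_T_ACCOM_MEAN = 1.0
#: A-site arrival mean at the 50 nM reference concentration; scales as 1/conc
_T_ARRIVAL_AT_50NM = 10.0
#: per-channel photobleaching hazard (1/s); small so bleaching is a minor censoring mode
_BLEACH_RATE = 1e-4


def make_preset(
    name: str,
    tc_phe_nM: float = 50.0,
    sup_tc_uM: float = 1.0,
    **overrides,
) -> KineticPreset:
    """Return the registered kinetic preset for a condition.

    Parameters
    ----------
    name
        Condition label; one of ``UTu1``, ``supD``, ``Ser``, ``UTu1A``.
    tc_phe_nM
        Concentration of the dye-labelled ternary complex, in nM.  The
        A-site arrival dwell scales inversely with it; registered branch
        probabilities measured at a non-reference concentration (UTu1 at
        200 nM) are applied when the concentration matches.
    sup_tc_uM
        Concentration of the suppressor ternary complex, in uM; the
        suppression-codon decoding dwell scales inversely with it.
    overrides
        Field-level overrides applied on top of the registry values
        (e.g. ``bleach_rate_green=0.0`` for noise-free experiments).
    """
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(_REGISTRY)}"
        )
    if tc_phe_nM <= 0 or sup_tc_uM <= 0:
        raise ValueError("concentrations must be positive")
    entry = dict(_REGISTRY[name])
    conc_overrides = entry.pop("overrides")
    if tc_phe_nM in conc_overrides:
        entry.update(conc_overrides[tc_phe_nM])
    t_decode = entry.pop("t_decode_sup_1uM") / sup_tc_uM
    fields = dict(
        preset_id=f"{name}@{tc_phe_nM:g}nM",
        name=name,
        tc_phe_conc=tc_phe_nM,
        sup_tc_conc=sup_tc_uM,
        t_join_mean=_T_JOIN_MEAN,
        t_arrival_mean=_T_ARRIVAL_AT_50NM * 50.0 / tc_phe_nM,
        t_accom_mean=_T_ACCOM_MEAN,
        t_decode_sup_mean=t_decode,
        t_rotated_mean=_T_ROTATED_MEAN,
        t_disassembly_mean=_T_DISASSEMBLY_MEAN,
        p_continue_late=0.95,
        p_mode_50S=0.5,
        bleach_rate_green=_BLEACH_RATE,
        bleach_rate_red=_BLEACH_RATE,
        **entry,
    )
    fields.update(overrides)
    return KineticPreset(**fields)


def expected_fractions(preset: KineticPreset) -> dict:
    """Closed-form pathway probabilities implied by a preset.

    These are exact branch products (no sampling, no censoring) and serve
    as the oracle for Monte-Carlo recovery: conditional on decoding the
    suppression codon, the ribosome disassembles pre-translocation with
    probability ``p_pre_dis``; otherwise the post-translocation triple
    applies.
    """
    pre = preset.p_pre_dis
    post = preset.p_post
    return {
        "p_decode_codon2": preset.p_decode_sup,
        "p_pre_dis_given_decode": pre,
        "p_post_dis_given_decode": (1.0 - pre) * post.disassemble,
        "p_survive_codon3_given_decode": (1.0 - pre) * post.continue_,
        "p_censor_given_decode": (1.0 - pre) * post.censor,
    }


@dataclass
class Interval:
    """One mechanistic interval of a trajectory: constant state and red-dye count."""

    state: str
    codon: int | None
    t_start: float
    t_end: float
    cy5_count: int

    def to_record(self) -> dict:
        return {
            "state": self.state,
            "codon": self.codon,
            "t_start": self.t_start,
            "t_end": self.t_end,
            "cy5_count": self.cy5_count,
        }


@dataclass
class Trajectory:
    """Ground-truth mechanistic path of one ribosome over the movie."""

    trace_id: str
    preset_id: str
    intervals: list[Interval]
    outcome_truth: str
    last_codon_truth: int
    red_bleach_time: float | None = None
    green_bleach_time: float | None = None

    def validate(self) -> None:
        ivs = self.intervals
        if not ivs or ivs[0].state != PIC or ivs[0].t_start != 0.0:
            raise ValueError("trajectory must start in the pre-initiation state at t=0")
        prev_end = 0.0
        for iv in ivs:
            if not math.isclose(iv.t_start, prev_end, abs_tol=1e-9):
                raise ValueError("intervals must be contiguous")
            if iv.t_end < iv.t_start:
                raise ValueError("intervals must have nonnegative duration")
            prev_end = iv.t_end
        # a bleach is the only non-PIC signal allowed before delivery
        if any(
            iv.state not in (PIC, BLEACHED) and iv.t_start < DELIVERY_TIME - 1e-9
            for iv in ivs
        ):
            raise ValueError("no post-delivery state may begin before delivery")


def _exp(rng: np.random.Generator, mean: float) -> float:
    return float(rng.exponential(mean))


def _dwell(rng: np.random.Generator, mean: float, floor: float) -> float:
    """Shifted-exponential dwell with the given overall mean."""
    if mean <= floor:
        return mean
    return floor + float(rng.exponential(mean - floor))


def sample_trajectory(
    program: CodonProgram,
    preset: KineticPreset,
    rng: np.random.Generator,
    trace_id: str = "trace",
) -> Trajectory:
    """Sample one ground-truth trajectory from a preset.

    At each decision point the branch is drawn from the preset
    probabilities, then the dwell from an exponential with the
    branch-specific mean.  Each dye-labelled tRNA raises the red-dye
    count on A-site arrival and lowers it two elongation cycles later,
    when it is translocated out of the P site.  The trajectory is
    right-censored at movie end; a green-dye bleach before the terminal
    mechanistic event truncates the trajectory into a BLEACHED tail.
    """
    # bleach clocks are drawn first so the draw sequence is stable
    g_rate, r_rate = preset.bleach_rate_green, preset.bleach_rate_red
    t_green_bleach = _exp(rng, 1.0 / g_rate) if g_rate > 0 else math.inf
    red_bleach_wait = _exp(rng, 1.0 / r_rate) if r_rate > 0 else math.inf

    ivs: list[Interval] = []
    t = DELIVERY_TIME + _dwell(rng, preset.t_join_mean, preset.dwell_floor)
    ivs.append(Interval(PIC, None, 0.0, t, 0))
    cy5 = 0
    first_arrival: float | None = None
    outcome = "COMPLETED"
    post = preset.p_post
    sup_k = program.sup_index

    k = 1
    while k <= len(program):
        slot = program[k - 1]
        if slot.trna == "Sup":
            if rng.random() >= preset.p_decode_sup:
                ivs.append(Interval(STALLED, k, t, math.inf, cy5))
                outcome = STALLED
                break
            dwell = _dwell(rng, preset.t_decode_sup_mean, preset.dwell_floor)
            ivs.append(Interval(NONROT, k, t, t + dwell, cy5))
            t += dwell
        else:
            if k >= 4 and rng.random() >= preset.p_continue_late:
                ivs.append(Interval(STALLED, k, t, math.inf, cy5))
                outcome = STALLED
                break
            arrival = _dwell(rng, preset.t_arrival_mean, preset.dwell_floor)
            ivs.append(Interval(NONROT, k, t, t + arrival, cy5))
            t += arrival
            cy5 += 1
            if first_arrival is None:
                first_arrival = t
            accom = _dwell(rng, preset.t_accom_mean, preset.dwell_floor)
            ivs.append(Interval(NONROT, k, t, t + accom, cy5))
            t += accom

        # rotation: codon k is decoded
        if k == sup_k and rng.random() < preset.p_pre_dis:
            dwell = _dwell(rng, preset.t_disassembly_mean, preset.dwell_floor)
            ivs.append(Interval(ROT, k, t, t + dwell, cy5))
            t += dwell
            mode = DIS_50S if rng.random() < preset.p_mode_50S else DIS_70S
            ivs.append(Interval(mode, None, t, math.inf, 0))
            outcome = mode
            break
        dwell = _dwell(rng, preset.t_rotated_mean, preset.dwell_floor)
        ivs.append(Interval(ROT, k, t, t + dwell, cy5))
        t += dwell
        # translocation ends cycle k; the tRNA that decoded codon k-1
        # moves P -> E and departs (two-cycle occupancy)
        if k >= 2 and program[k - 2].dye_labeled:
            cy5 -= 1
        if k == sup_k:
            u = rng.random()
            if u < post.disassemble:
                dwell = _dwell(rng, preset.t_disassembly_mean, preset.dwell_floor)
                ivs.append(Interval(NONROT, k + 1, t, t + dwell, cy5))
                t += dwell
                mode = DIS_50S if rng.random() < preset.p_mode_50S else DIS_70S
                ivs.append(Interval(mode, None, t, math.inf, 0))
                outcome = mode
                break
            if u < post.disassemble + post.censor:
                ivs.append(Interval(STALLED, k + 1, t, math.inf, cy5))
                outcome = STALLED
                break
        k += 1
    else:
        # all codons translocated: non-rotated idle until movie end
        ivs.append(Interval(NONROT, len(program) + 1, t, math.inf, cy5))

    red_bleach = None
    if first_arrival is not None and math.isfinite(red_bleach_wait):
        rb = first_arrival + red_bleach_wait
        if rb < MOVIE_LENGTH:
            red_bleach = rb

    return _finalize(ivs, outcome, t_green_bleach, red_bleach, preset, program, trace_id)


def _finalize(
    ivs: list[Interval],
    outcome: str,
    t_green_bleach: float,
    red_bleach: float | None,
    preset: KineticPreset,
    program: CodonProgram,
    trace_id: str,
) -> Trajectory:
    """Apply green-bleach truncation and movie-end censoring; derive truth labels."""
    # a bleach can truncate a stalled or idle tail, but not a trajectory
    # whose disassembly signature already fired
    if outcome in (DIS_50S, DIS_70S):
        terminal_start = ivs[-1].t_start
    else:
        terminal_start = math.inf
    green_bleach = None
    if t_green_bleach < min(terminal_start, MOVIE_LENGTH):
        clipped = []
        for iv in ivs:
            if iv.t_start >= t_green_bleach:
                break
            clipped.append(
                Interval(iv.state, iv.codon, iv.t_start, min(iv.t_end, t_green_bleach), iv.cy5_count)
            )
        clipped.append(Interval(BLEACHED, None, t_green_bleach, MOVIE_LENGTH, 0))
        ivs = clipped
        outcome = BLEACHED
        green_bleach = t_green_bleach
    else:
        clipped = []
        for iv in ivs:
            if iv.t_start >= MOVIE_LENGTH:
                # terminal event fell beyond the movie: censored mid-path
                if iv.t_end == math.inf and outcome in (DIS_50S, DIS_70S, STALLED):
                    outcome = "CENSORED_END"
                break
            end = min(iv.t_end, MOVIE_LENGTH)
            if iv.t_end > MOVIE_LENGTH and iv.t_end != math.inf:
                # a mid-path dwell ran past the movie
                if outcome == "COMPLETED":
                    outcome = "CENSORED_END"
            clipped.append(Interval(iv.state, iv.codon, iv.t_start, end, iv.cy5_count))
        ivs = clipped
        if outcome == "COMPLETED" and ivs[-1].state != NONROT:
            outcome = "CENSORED_END"
        if ivs and ivs[-1].t_end < MOVIE_LENGTH:
            # interrupted mid-dwell by the clip above
            last = ivs[-1]
            ivs[-1] = Interval(last.state, last.codon, last.t_start, MOVIE_LENGTH, last.cy5_count)

    last_codon = 0
    for iv in ivs:
        if iv.state == ROT and iv.codon is not None:
            last_codon = max(last_codon, iv.codon)
    if outcome == BLEACHED and last_codon == len(program):
        # translation finished before the dye died
        outcome = "COMPLETED"

    traj = Trajectory(
        trace_id=trace_id,
        preset_id=preset.preset_id,
        intervals=ivs,
        outcome_truth=outcome,
        last_codon_truth=last_codon,
        red_bleach_time=red_bleach,
        green_bleach_time=green_bleach,
    )
    traj.validate()
    return traj
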