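"""Kinetic parameter sets and DNA substrate geometry for the gated-scanner model.

The gated scanner is a translocating helicase-nuclease (AddAB) that moves along
dsDNA at a constant pre-recognition rate, scans for Chi hotspot sequences, and
may convert into a Chi-modified state (AddAB*) that translocates more slowly and
binds the Chi sequence stably.  Each enzyme variant (wild type, the ionic-latch
mutant E129A, the Chi-binding mutants F68A/F210A, and their double mutants) is
a point in the same parameter space; the packaged defaults reproduce the
measured observables for each variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import gamma as _gamma_dist
from scipy.optimize import brentq


@dataclass(frozen=True)
class EnzymeParams:
    """Kinetic parameters of one enzyme variant under the gated-scanner model.

    Parameters
    ----------
    name : str
        Variant label (free-form).
    v_pre : float
        Translocation rate before Chi recognition, bp/s.  Must be > 0.
    v_post : float
        Translocation rate after conversion to the Chi-modified state, bp/s.
    p_pause : float
        Probability of forming a stalled encounter complex per Chi sequence
        encountered while still in the pre-Chi state (0-1).
    pause_shape : int
        Number of sequential kinetic sub-steps of the pause; the pause dwell
        is gamma-distributed with this integer shape (>= 1).
    pause_scale : float
        Per-step mean dwell of the pause, seconds.
    p_commit : float
        Probability that a pause ends in commitment to the Chi-modified state
        rather than release back into the scanning state (0-1).
    k_off_chi : float
        Dissociation rate of the mature enzyme:Chi complex, per minute.
        Measured by the exonuclease-chase assay; half-life = ln2 / k_off_chi.
    k_iso : float
        Spontaneous (Chi-independent) isomerization rate into the Chi-modified
        state during translocation, per second of pre-Chi translocation time.
        Zero for wild type; non-zero for the latch mutant.
    k_detach : float
        Detachment hazard during translocation, per second; controls
        processivity (mean translocated distance ~ v / k_detach).
    """

    name: str
    v_pre: float
    v_post: float
    p_pause: float
    pause_shape: int = 2
    pause_scale: float = 0.5
    p_commit: float = 0.5
    k_off_chi: float = math.log(2) / 3.0
    k_iso: float = 0.0
    k_detach: float = 0.0

    def __post_init__(self) -> None:
        if not self.v_pre > 0:
            raise ValueError("v_pre must be > 0")
        for attr in ("v_post", "pause_scale", "k_off_chi", "k_iso", "k_detach"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        for attr in ("p_pause", "p_commit"):
            val = getattr(self, attr)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{attr} must be in [0, 1]")
        if int(self.pause_shape) != self.pause_shape or self.pause_shape < 1:
            raise ValueError("pause_shape must be an integer >= 1")

    @property
    def t_half_chi_min(self) -> float:
        """Half-life of the enzyme:Chi complex, minutes."""
        return math.log(2) / self.k_off_chi

    @property
    def chi_commitment(self) -> float:
        """Per-Chi-encounter probability of conversion to the slow state."""
        return self.p_pause * self.p_commit

    def with_(self, **overrides) -> "EnzymeParams":
        """Return a copy with selected fields replaced."""
        return replace(self, **overrides)


@dataclass(frozen=True)
class SubstrateSpec:
    """Geometry of a linear dsDNA substrate, 0-based bp from the enzyme entry end.

    Positions are half-open in [0, length_bp).  ``chi_positions`` must be
    strictly increasing; ``triplex_pos`` (the reporter triplex for stopped-flow
    displacement assays), when set, must lie beyond the last Chi.
    """

    length_bp: float
    chi_positions: tuple = ()
    triplex_pos: float | None = None
    blocked_far_end: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "chi_positions", tuple(float(c) for c in self.chi_positions))
        if self.length_bp <= 0:
            raise ValueError("length_bp must be > 0")
        for pos in self.chi_positions:
            if not 0 < pos < self.length_bp:
                raise ValueError("every Chi position must lie inside (0, length_bp)")
        if any(b <= a for a, b in zip(self.chi_positions, self.chi_positions[1:])):
            raise ValueError("chi_positions must be strictly increasing")
        if self.triplex_pos is not None:
            if not 0 < self.triplex_pos < self.length_bp:
                raise ValueError("triplex_pos must lie inside (0, length_bp)")
            if self.chi_positions and self.triplex_pos <= max(self.chi_positions):
                raise ValueError("triplex_pos must lie beyond the last Chi position")


def per_chi_probability(locus_frequency: float, n_chi: int = 10) -> float:
    """Convert a locus-level pause frequency to a per-Chi pause probability.

    A locus of ``n_chi`` independent Chi sequences produces at least one pause
    with probability ``1 - (1 - p)**n_chi``; inverting gives
    ``p = 1 - (1 - f)**(1/n_chi)``.
    """
    if not 0 <= locus_frequency <= 1:
        raise ValueError("locus_frequency must be in [0, 1]")
    return 1.0 - (1.0 - locus_frequency) ** (1.0 / n_chi)


def pause_scale_for_censored_median(
    median_s: float, shape: int = 2, min_pause_s: float = 0.33
) -> float:
    """Gamma scale such that the dwell median, conditional on exceeding the
    detection limit ``min_pause_s``, equals ``median_s``.

    This is the analytic (infinite-data, ideal-detector) calibration; the
    packaged variant scales additionally absorb the small quantization bias of
    the run-length detector (see docs/methods.md).
    """
    if median_s <= min_pause_s:
        raise ValueError("target median must exceed the detection limit")

    def _resid(theta: float) -> float:
        g = _gamma_dist(shape, scale=theta)
        return g.ppf(0.5 * (1.0 + g.cdf(min_pause_s))) - median_s

    # below ~censor/20 the whole distribution sits under the censor and the
    # conditional median degenerates; bracket above that
    return brentq(_resid, min_pause_s / 20.0, 10.0 * median_s)


# ---------------------------------------------------------------------------
# Packaged substrates
# ---------------------------------------------------------------------------

def chi10_substrate(
    length_bp: float = 7700.0, first_chi_bp: float = 4588.0, spacing_bp: float = 30.0
) -> SubstrateSpec:
    """The single-molecule translocation substrate: ~7.7 kb with a locus of
    ten closely spaced Chi sequences starting 4588 bp from the entry point.

    The intra-locus spacing is not resolved by the instrument; 30 bp is the
    package default and is configurable.
    """
    chis = tuple(first_chi_bp + i * spacing_bp for i in range(10))
    return SubstrateSpec(length_bp=length_bp, chi_positions=chis)


def triplex_substrate(
    n_chi: int = 3,
    triplex_pos: float = 6000.0,
    first_chi_bp: float = 800.0,
    spacing_bp: float = 30.0,
    length_bp: float = 6500.0,
) -> SubstrateSpec:
    """Stopped-flow triplex-displacement substrate: an optional Chi locus
    between the entry end and a single downstream triplex reporter; the far
    end is blocked so entry is unidirectional.

    The default places the reporter several kb beyond the Chi locus so that
    the slow (Chi-modified) population is delayed by well over a second
    relative to the fast phase and the two phases are resolvable.
    """
    chis = tuple(first_chi_bp + i * spacing_bp for i in range(n_chi))
    return SubstrateSpec(
        length_bp=length_bp,
        chi_positions=chis,
        triplex_pos=triplex_pos,
        blocked_far_end=True,
    )


# ---------------------------------------------------------------------------
# Packaged enzyme variants
# ---------------------------------------------------------------------------

_LN2 = math.log(2)

# Per-Chi commitment probabilities (p_pause * p_commit) implied by the ensemble
# assays at 37 C: the wild type converts ~50% of the population on a 3-Chi
# substrate and the latch mutant ~70%, so c = 1 - (1 - converted)**(1/3).
_C_WT = 1.0 - 0.5 ** (1.0 / 3.0)      # ~0.2063
_C_E129A = 1.0 - 0.3 ** (1.0 / 3.0)   # ~0.3306

# 22 C single-molecule calibration.  The printed locus pause frequencies
# (66% / 57%) and censored medians (1.45 s / 1.00 s) are DETECTED quantities:
# dwells below the 0.33 s instrument resolution are lost.  The packaged
# underlying locus frequencies and gamma scales are therefore calibrated by
# Monte-Carlo through the full simulate -> filter -> detect pipeline so that
# the detected frequency and the median over an assay-sized ensemble land on
# the printed values.  (The analytic conditional-gamma calibration,
# pause_scale_for_censored_median, gives 0.814 and 0.527; the differences
# reflect detector response, event splitting/merging and small-ensemble
# median bias.)
_F_LOCUS_WT_22C = 0.715      # detected locus frequency 0.66
_F_LOCUS_E129A_22C = 0.675   # detected locus frequency 0.57
_SCALE_WT_22C = 0.74
_SCALE_E129A_22C = 0.45

_VARIANTS: dict[str, EnzymeParams] = {}
_VARIANT_NOTES: dict[str, dict[str, str]] = {}


def _register(params: EnzymeParams, notes: dict[str, str]) -> None:
    _VARIANTS[params.name] = params
    _VARIANT_NOTES[params.name] = notes


_register(
    EnzymeParams(
        name="wildtype",
        v_pre=300.0,
        v_post=225.0,
        p_pause=per_chi_probability(_F_LOCUS_WT_22C),
        pause_shape=2,
        pause_scale=_SCALE_WT_22C,
        p_commit=0.5,
        k_off_chi=_LN2 / 3.0,
        k_iso=0.0,
        k_detach=0.01,
    ),
    {
        "v_pre": "mean pre-Chi translocation rate ~300 bp/s at 22 C",
        "v_post": "slightly decreased post-Chi rate; package default 0.75*v_pre",
        "p_pause": "calibrated: 66% of traces show a detectable pause at the 10-Chi locus",
        "pause_shape": "non-exponential dwell -> 2 sequential kinetic steps",
        "pause_scale": "calibrated so censored median detected pause = 1.45 s",
        "p_commit": "split of encounters into failed vs successful attempts (convention)",
        "k_off_chi": "chase half-life of the wild-type enzyme:Chi complex ~3 min",
        "k_iso": "no spontaneous conversion on Chi-free DNA for wild type",
        "k_detach": "high processivity: mean run ~30 kb at 300 bp/s",
    },
)

_register(
    _VARIANTS["wildtype"].with_(
        name="E129A",
        p_pause=per_chi_probability(_F_LOCUS_E129A_22C),
        pause_scale=_SCALE_E129A_22C,
        k_off_chi=_LN2 / 45.0,
    ),
    {
        "v_pre": "latch mutant translocates at the same ~300 bp/s pre-Chi rate",
        "v_post": "slightly decreased post-Chi rate; package default 0.75*v_pre",
        "p_pause": "calibrated: 57% of latch-mutant traces show a detectable locus pause",
        "pause_shape": "same two-step pause law as wild type",
        "pause_scale": "calibrated so censored median detected pause = 1.00 s",
        "p_commit": "split convention shared with wild type",
        "k_off_chi": "chase half-life ~45 min (15-fold stabilized vs wild type)",
        "k_iso": "spontaneous conversion measured at 37 C; negligible in the 22 C traces",
        "k_detach": "high processivity, wild-type-like",
    },
)

_register(
    EnzymeParams(
        name="wildtype_37C",
        v_pre=1000.0,
        v_post=750.0,
        p_pause=0.5,
        pause_shape=2,
        pause_scale=0.10,
        p_commit=_C_WT / 0.5,
        k_off_chi=_LN2 / 3.0,
        k_iso=0.0,
        k_detach=0.005,
    ),
    {
        "v_pre": "mean translocation rate ~1000 bp/s at 37 C",
        "v_post": "0.75*v_pre post-Chi convention",
        "p_pause": "encounter probability convention at 37 C (see methods)",
        "pause_shape": "two-step pause law",
        "pause_scale": "pauses markedly shortened at 37 C, mostly below the 0.33 s limit",
        "p_commit": "per-Chi commitment 1-0.5^(1/3): ~50% converted on the 3-Chi substrate",
        "k_off_chi": "chase half-life ~3 min (chase assays run at 37 C)",
        "k_iso": "no spontaneous conversion on Chi-free DNA for wild type",
        "k_detach": "high processivity",
    },
)

_register(
    _VARIANTS["wildtype_37C"].with_(
        name="E129A_37C",
        pause_scale=0.05,
        p_commit=_C_E129A / 0.5,
        k_off_chi=_LN2 / 45.0,
        k_iso=0.1,
    ),
    {
        "v_pre": "~1000 bp/s at 37 C, same as wild type",
        "v_post": "0.75*v_pre post-Chi convention",
        "p_pause": "encounter probability convention shared with wild type",
        "pause_shape": "two-step pause law",
        "pause_scale": "latch-mutant pauses at 37 C always below the 0.33 s detection limit",
        "p_commit": "per-Chi commitment 1-0.3^(1/3): ~70% converted on the 3-Chi substrate",
        "k_off_chi": "chase half-life ~45 min",
        "k_iso": "first-phase triplex amplitude decays with distance on Chi-free DNA",
        "k_detach": "high processivity (absolute triplex amplitudes wild-type-like)",
    },
)

_register(
    _VARIANTS["wildtype_37C"].with_(
        name="F68A",
        p_pause=0.5 / 2.5,
        k_off_chi=_LN2 / 0.8,
    ),
    {
        "v_pre": "Chi-binding mutants resect Chi-free DNA like wild type",
        "v_post": "0.75*v_pre convention",
        "p_pause": "moderate Chi-fragment yield defect, ~2.5-fold below wild type",
        "pause_shape": "two-step pause law",
        "pause_scale": "wild-type 37 C pause law",
        "p_commit": "wild-type commitment; yield defect carried by the encounter step",
        "k_off_chi": "chase half-life ~0.8 min (faster than wild type)",
        "k_iso": "no spontaneous conversion",
        "k_detach": "high processivity",
    },
)

_register(
    _VARIANTS["wildtype_37C"].with_(
        name="F210A",
        p_pause=0.5 / 15.0,
    ),
    {
        "v_pre": "Chi-binding mutants resect Chi-free DNA like wild type",
        "v_post": "0.75*v_pre convention",
        "p_pause": "severe Chi-fragment yield defect, ~15-fold below wild type",
        "pause_shape": "two-step pause law",
        "pause_scale": "wild-type 37 C pause law",
        "p_commit": "wild-type commitment; yield defect carried by the encounter step",
        "k_off_chi": "not measurable for this variant; wild-type value assumed",
        "k_iso": "no spontaneous conversion",
        "k_detach": "high processivity",
    },
)

_register(
    _VARIANTS["wildtype_37C"].with_(
        name="F68A+E129A",
        k_off_chi=_LN2 / 13.0,
        k_iso=0.1,
    ),
    {
        "v_pre": "same pre-Chi rate as wild type",
        "v_post": "0.75*v_pre convention",
        "p_pause": "Chi-fragment yield rescued to wild-type level by the latch mutation",
        "pause_shape": "two-step pause law",
        "pause_scale": "wild-type 37 C pause law",
        "p_commit": "wild-type per-Chi commitment (rescued yield)",
        "k_off_chi": "chase half-life ~13 min (~15-fold stabilized vs F68A)",
        "k_iso": "latch destabilized: spontaneous conversion as in E129A",
        "k_detach": "high processivity",
    },
)

_register(
    _VARIANTS["wildtype_37C"].with_(
        name="F210A+E129A",
        p_pause=4.0 * 0.5 / 15.0,
        k_iso=0.1,
    ),
    {
        "v_pre": "same pre-Chi rate as wild type",
        "v_post": "0.75*v_pre convention",
        "p_pause": "partial rescue of the severe yield defect (package choice: 4x over F210A)",
        "pause_shape": "two-step pause law",
        "pause_scale": "wild-type 37 C pause law",
        "p_commit": "wild-type commitment convention",
        "k_off_chi": "not measurable for F210A backgrounds; wild-type value assumed",
        "k_iso": "latch destabilized: spontaneous conversion as in E129A",
        "k_detach": "high processivity",
    },
)


def list_variants() -> list[str]:
    """Names of all packaged enzyme parameter sets."""
    return sorted(_VARIANTS)


def make_default_params(variant_name: str) -> EnzymeParams:
    """Return the packaged parameter set for a named enzyme variant.

    Packaged variants: wildtype, E129A (22 C single-molecule sets),
    wildtype_37C, E129A_37C, F68A, F210A, F68A+E129A, F210A+E129A (37 C
    ensemble-assay sets).  Each field's provenance note is available through
    :func:`variant_notes`.
    """
    try:
        return _VARIANTS[variant_name]
    except KeyError:
        raise KeyError(
            f"unknown variant {variant_name!r}; known: {', '.join(list_variants())}"
        ) from None


def variant_notes(variant_name: str) -> dict[str, str]:
    """Per-field provenance notes (observable each default reproduces)."""
    if variant_name not in _VARIANT_NOTES:
        raise KeyError(f"unknown variant {variant_name!r}")
    return dict(_VARIANT_NOTES[variant_name])
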