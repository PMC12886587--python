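"""Synthetic whole-body TAC cohorts with the statistical structure the
network pipelines are designed to detect.

The generator emulates a two-arm tracer study: a control arm and a
perturbation arm in which hepatic uptake of the tracer is pharmacologically
inhibited.  Per region the curve is a mixture of a shared vascular input and
an organ-specific accumulation term:

* blood pool (aorta, ventricle): an early gamma-variate bolus peak plus a
  slowly equilibrating tail; the curve *shape* is identical in both arms.
  The perturbation arm's blood amplitude is scaled by ``blood_effect``,
  reflecting redistribution of tracer from liver to blood; time-course
  correlations are unaffected by a pure amplitude change.
* liver: vascular component plus a saturating uptake term whose amplitude is
  multiplied by ``liver_effect`` in the perturbation arm (inhibited uptake)
  and by a per-subject lognormal factor (transporter-abundance variability).
* gallbladder: vascular background plus a filling ramp with random onset and
  a heavy-tailed lognormal amplitude — extreme inter-subject variability in
  both arms, independent of treatment.
* kidneys, myocardium, pancreas, aorta wall: low-amplitude mixtures of blood
  and slow uptake.

Inter-subject variation has four sources: a shared per-subject scale (dose /
body-habitus normalisation imperfection, which induces positive interregional
correlations in the reference cohort), a small per-region multiplicative
term, an additive region-independent background offset (spill-over-like; it
shifts static SUVs but is invisible to time-course correlation), and
per-frame multiplicative measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import DEFAULT_GRID, InterpolationSpec, RegionSUVTable, TACMatrix, interpolate_tac, static_suv

__all__ = ["CohortSpec", "Cohort", "generate_cohort", "make_fixture", "DEFAULT_REGIONS"]

DEFAULT_REGIONS = (
    "left kidney",
    "right kidney",
    "liver",
    "aorta",
    "aorta wall",
    "ventricle",
    "myocardium",
    "gallbladder",
    "pancreas",
)


def _default_times() -> np.ndarray:
    # 10 s frames over the abdominal mono-bed phase, then coarse whole-body
    # passes; deliberately irregular so the interpolation path is exercised.
    return np.concatenate([np.arange(10.0, 180.0, 10.0), np.arange(180.0, 2520.0, 120.0)])


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror the reference study design: 13 control and 9 perturbation
    subjects, nine organ regions, ~40-minute irregularly sampled scans, a
    65 % reduction of hepatic uptake under perturbation, a modest rise in
    blood amplitude, and extreme gallbladder variability in both arms.
    """

    n_control: int = 13
    n_perturb: int = 9
    regions: tuple = DEFAULT_REGIONS
    raw_times: np.ndarray = field(default_factory=_default_times)
    liver_effect: float = 0.35
    blood_effect: float = 1.15
    liver_biovar: float = 0.05
    gallbladder_cv: float = 1.5
    subject_noise: float = 0.03
    background_noise: float = 0.12
    shared_noise: float = 0.15
    kinetic_jitter: float = 0.10
    measurement_noise: float = 0.02
    control_label: str = "control"
    perturb_label: str = "rifampicin"
    seed: int = 0

    def __post_init__(self):
        if self.n_control < 3 or self.n_perturb < 1:
            raise ValueError("need n_control >= 3 and n_perturb >= 1")
        for name in (
            "liver_effect",
            "blood_effect",
            "gallbladder_cv",
            "subject_noise",
            "background_noise",
            "shared_noise",
            "kinetic_jitter",
            "measurement_noise",
            "liver_biovar",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        t = np.asarray(self.raw_times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("raw_times must be strictly increasing")
        if t[0] > DEFAULT_GRID.t_start or t[-1] < DEFAULT_GRID.t_end:
            raise ValueError(
                "raw_times must cover the standard interpolation span "
                f"[{DEFAULT_GRID.t_start:g}, {DEFAULT_GRID.t_end:g}] s"
            )
        object.__setattr__(self, "raw_times", t)
        object.__setattr__(self, "regions", tuple(self.regions))


@dataclass(frozen=True)
class Cohort:
    """Generated cohort: one TACMatrix per region plus the derived statics."""

    tacs: dict
    suv_table: RegionSUVTable
    spec: CohortSpec

    def blood_pool(self) -> TACMatrix:
        from .core import combine_regions

        return combine_regions([self.tacs["aorta"], self.tacs["ventricle"]])


def _gamma_variate(t: np.ndarray, t_peak: float, shape: float = 2.0) -> np.ndarray:
    x = np.clip(t / t_peak, 1e-12, None)
    return x**shape * np.exp(shape * (1.0 - x))


def generate_cohort(
    spec: CohortSpec = CohortSpec(), grid: InterpolationSpec = DEFAULT_GRID
) -> Cohort:
    """Simulate raw TACs, resample them onto the standard grid, derive statics.

    Deterministic under ``spec.seed``: the same spec yields bit-identical
    cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    t = spec.raw_times
    n = spec.n_control + spec.n_perturb
    groups = [spec.control_label] * spec.n_control + [spec.perturb_label] * spec.n_perturb
    subject_ids = [f"c{i+1:02d}" for i in range(spec.n_control)] + [
        f"r{i+1:02d}" for i in range(spec.n_perturb)
    ]
    sig_gb = np.sqrt(np.log(1.0 + spec.gallbladder_cv**2))
    shared = rng.lognormal(0.0, spec.shared_noise, n)

    raw = {r: np.zeros((n, t.size)) for r in spec.regions}
    for s in range(n):
        perturbed = groups[s] == spec.perturb_label
        jit = rng.lognormal(0.0, spec.kinetic_jitter, 4)
        liver_bio = rng.lognormal(0.0, spec.liver_biovar)
        blood_scale = spec.blood_effect if perturbed else 1.0
        blood = blood_scale * (
            11.0 * _gamma_variate(t, 60.0 * jit[0])
            + 1.2 * (1.0 - np.exp(-t / (300.0 * jit[1])))
        )

        def uptake(amplitude, tau):
            return amplitude * (1.0 - np.exp(-t / tau))

        liver_amp = 12.0 * liver_bio * (spec.liver_effect if perturbed else 1.0)
        base = {
            "left kidney": 0.8 * blood + uptake(3.5, 400.0 * jit[2]),
            "right kidney": 0.8 * blood + uptake(3.5, 420.0 * jit[2]),
            "liver": 0.4 * blood + uptake(liver_amp, 500.0 * jit[3]),
            "aorta": blood,
            "aorta wall": 0.35 * blood + uptake(0.4, 700.0),
            "ventricle": 0.97 * blood,
            "myocardium": 0.5 * blood + uptake(0.8, 600.0),
            "gallbladder": 0.2 * blood,
            "pancreas": 0.45 * blood + uptake(0.8, 500.0),
        }
        onset = rng.uniform(500.0, 1900.0)
        amp = rng.lognormal(np.log(7.0), sig_gb)
        base["gallbladder"] = base["gallbladder"] + amp * np.clip(
            (t - onset) / (grid.t_end - onset), 0.0, 1.0
        )
        background = rng.normal(0.0, spec.background_noise, len(spec.regions))
        for ri, region in enumerate(spec.regions):
            if region not in base:
                raise KeyError(f"no kinetic model for region {region!r}")
            curve = base[region] * shared[s] * rng.lognormal(0.0, spec.subject_noise)
            curve = curve + background[ri]
            curve = curve * (1.0 + spec.measurement_noise * rng.standard_normal(t.size))
            raw[region][s] = np.clip(curve, 0.0, None)

    tacs = {}
    statics = np.empty((n, len(spec.regions)))
    for ri, region in enumerate(spec.regions):
        interp = np.array([interpolate_tac(t, raw[region][s], grid) for s in range(n)])
        tacs[region] = TACMatrix(
            region_label=region,
            subject_ids=subject_ids,
            group_labels=groups,
            time_grid=grid.grid,
            values=interp,
        )
        statics[:, ri] = [static_suv(interp[s], grid) for s in range(n)]
    table = RegionSUVTable(
        subject_ids=subject_ids,
        group_labels=groups,
        region_labels=spec.regions,
        values=statics,
    )
    return Cohort(tacs=tacs, suv_table=table, spec=spec)


_FIXTURES = {
    # the reference study design: 13 + 9 subjects, liver inhibition,
    # hypervariable gallbladder
    "paper-default": {},
    # all group effects off; inter-subject structure otherwise unchanged
    "null": {"liver_effect": 1.0, "blood_effect": 1.0},
    # exaggerated contrast guaranteeing two-component s-network separation
    "strong-effect": {"liver_effect": 0.15, "blood_effect": 1.3},
}


def make_fixture(name: str, seed: int = 0) -> CohortSpec:
    """Documented preset cohort specifications."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; options: {sorted(_FIXTURES)}")
    return replace(CohortSpec(seed=seed), **_FIXTURES[name])
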