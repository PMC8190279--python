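"""Seeded generator of fluorescence-time datasets emulating the study design.

The generator evaluates the one-compartment closed form for each
(compound, route, time, replicate) cell, multiplies by the compound's
fluorescence yield, applies mean-one multiplicative noise and, for
injection-bearing routes, an optional early-timepoint quenching
attenuation (self-quenching of the concentrated depot right after
microinjection depresses the signal before the compound disperses).
Everything is deterministic for a fixed seed, with an independent
substream per (compound, route) so adding a compound never perturbs the
draws of the others.

The module also carries the study's reference inputs: the seven-compound
descriptor panel and the per-compound (ke, Q) reference values, which
serve both as simulation ground truth and as inputs to the downstream
exposure and QSPkR stages.
"""

from __future__ import annotations

import enum
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_pk import (
    DEFAULT_SAMPLING_TIMES_H,
    CompoundRecord,
    ExposureRegimen,
    PKParameters,
    Route,
    amount_at_time,
)

__all__ = [
    "NoiseModel",
    "QuenchSpec",
    "Dataset",
    "DATASET_COLUMNS",
    "study_compounds",
    "reference_rate_constants",
    "reference_pk_parameters",
    "default_study_design",
    "simulate_dataset",
    "generate_compound_panel",
]

DATASET_COLUMNS = ("compound", "route", "time_h", "replicate", "rfu", "censored")

#: immersion concentration (µM) and injected dose (mg/kg) used throughout
STUDY_CONC_UM = 10.0
STUDY_DOSE_MG_PER_KG = 2.0
STUDY_N_REPLICATES = 10

# The seven-compound panel: MW (g/mol), experimental LogD
# (octanol/Danieau), TPSA (Å^2), molar refractivity, H-bond
# acceptor/donor counts, rotatable bonds, imaging filter set.
_PANEL = [
    # name,       MW,      LogD,  TPSA,    MR,     HBA, HBD, rotor, channel
    ("S-CY3A",    691.9,  -1.96, 152.68, 180.42,   7,  1, 13, "dsRed"),
    ("S-CY5.5A", 1054.3,  -1.68, 256.18, 241.21,  13,  1, 18, "Cy5"),
    ("S-CY5A",    654.77, -0.72,  23.32, 185.18,   1,  0, 11, "Cy5"),
    ("FAMA",      413.38, -0.14, 105.09, 109.52,   6,  3,  3, "GFP"),
    ("TAMRA",     467.52,  0.46,  88.62, 135.27,   4,  1,  6, "dsRed"),
    ("R6GA",      462.6,   1.07,  38.33, 144.59,   2,  1,  7, "dsRed"),
    ("CY3A",      530.14,  1.73,  35.35, 169.95,   1,  1, 10, "dsRed"),
]

# Reference elimination rate constant ke (1/h) and passive exchange Q
# (L/h) per compound, from the whole-body fluorescence fits.
_REFERENCE_KE_Q = {
    "S-CY3A":   (0.012, 0.23e-9),
    "S-CY5.5A": (0.023, 0.34e-9),
    "S-CY5A":   (0.014, 1.61e-9),
    "FAMA":     (0.012, 1.71e-9),
    "TAMRA":    (0.052, 1.45e-9),
    "R6GA":     (0.011, 3.23e-9),
    "CY3A":     (0.049, 8.37e-9),
}

# Fluorescence yields are instrument- and compound-specific and cannot be
# compared across compounds; simulation truth uses arbitrary fixed values
# spread over the 1e3-1e4 RFU/ng range.
_DEFAULT_FLUOR = {
    "S-CY3A": 1500.0, "S-CY5.5A": 2500.0, "S-CY5A": 4000.0, "FAMA": 5500.0,
    "TAMRA": 7000.0, "R6GA": 8500.0, "CY3A": 9500.0,
}


def study_compounds() -> list[CompoundRecord]:
    """The seven fluorescent alkyne compounds with their descriptors."""
    return [
        CompoundRecord(name=n, mw=mw, logd=ld, tpsa=tp, mr=mr,
                       hba=a, hbd=d, rotor=r, channel=ch)
        for n, mw, ld, tp, mr, a, d, r, ch in _PANEL
    ]


def reference_rate_constants() -> dict[str, tuple[float, float]]:
    """Reference (ke 1/h, Q L/h) per compound from the published fits."""
    return dict(_REFERENCE_KE_Q)


def reference_pk_parameters() -> dict[str, PKParameters]:
    """Reference parameters with the default simulation fluorescence yields."""
    return {
        name: PKParameters(fluor=_DEFAULT_FLUOR[name], ke=ke, q=q)
        for name, (ke, q) in _REFERENCE_KE_Q.items()
    }


def default_study_design() -> tuple[list[CompoundRecord], list[ExposureRegimen], tuple[float, ...]]:
    """The study's exposure design.

    Seven compounds; immersion at 10 µM, PC and IP microinjection at
    2 mg/kg (0.5 ng into a 0.25 mg embryo), and the combination of
    immersion with a PC injection; sampled at 15 min and 1, 3, 6, 24,
    48 h.
    """
    regimens = [
        ExposureRegimen(route=Route.IMMERSION, medium_conc_um=STUDY_CONC_UM),
        ExposureRegimen(route=Route.PC, dose_mg_per_kg=STUDY_DOSE_MG_PER_KG),
        ExposureRegimen(route=Route.IP, dose_mg_per_kg=STUDY_DOSE_MG_PER_KG),
        ExposureRegimen(route=Route.COMBINATION, medium_conc_um=STUDY_CONC_UM,
                        dose_mg_per_kg=STUDY_DOSE_MG_PER_KG),
    ]
    return study_compounds(), regimens, DEFAULT_SAMPLING_TIMES_H


class NoiseDistribution(str, enum.Enum):
    LOGNORMAL = "lognormal-multiplicative"
    NORMAL = "normal-proportional"


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-level measurement noise.

    ``proportional_cv`` is the coefficient of variation of the
    multiplicative error.  The lognormal variant is parameterized to have
    mean exactly 1 (so large-n sample means converge to the model curve);
    the normal variant is 1 + cv·Z truncated at zero.  ``additive_floor``
    adds a zero-mean Gaussian background of that standard deviation (RFU),
    clipped so rfu stays nonnegative.
    """

    proportional_cv: float = 0.20
    additive_floor: float = 0.0
    distribution: NoiseDistribution = NoiseDistribution.LOGNORMAL

    def __post_init__(self) -> None:
        if self.proportional_cv < 0 or self.additive_floor < 0:
            raise ValueError("cv and additive floor must be nonnegative")
        object.__setattr__(self, "distribution", NoiseDistribution(self.distribution))

    def draw_factors(self, rng: np.random.Generator, n: int) -> np.ndarray:
        cv = self.proportional_cv
        if cv == 0:
            return np.ones(n)
        if self.distribution is NoiseDistribution.LOGNORMAL:
            sigma2 = np.log1p(cv * cv)
            # mean of lognormal(mu, sigma) is exp(mu + sigma^2/2) = 1
            return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)
        return np.maximum(1.0 + cv * rng.standard_normal(n), 0.0)


_DEFAULT_QUENCH_ROUTES = frozenset({Route.PC, Route.IP, Route.COMBINATION})


@dataclass(frozen=True)
class QuenchSpec:
    """Early-timepoint fluorescence quenching of injection depots.

    Right after microinjection the compound sits concentrated at the
    injection site and self-quenches; the measured signal is attenuated
    until the depot disperses.  Modelled as a fixed multiplicative
    attenuation applied to injection-bearing routes strictly before
    ``cutoff_time_h``.  Immersion observations are never attenuated.
    """

    affected_routes: frozenset[Route] = _DEFAULT_QUENCH_ROUTES
    cutoff_time_h: float = 1.0
    attenuation: float = 0.5

    def __post_init__(self) -> None:
        routes = frozenset(Route(r) for r in self.affected_routes)
        if Route.IMMERSION in routes:
            raise ValueError("immersion observations cannot quench")
        object.__setattr__(self, "affected_routes", routes)
        if not (0 < self.attenuation <= 1):
            raise ValueError("attenuation must be in (0, 1]")
        if self.cutoff_time_h < 0:
            raise ValueError("cutoff time must be nonnegative")

    def applies(self, route: Route, time_h: "float | np.ndarray"):
        in_route = Route(route) in self.affected_routes
        return in_route & (np.asarray(time_h) < self.cutoff_time_h)


@dataclass
class Dataset:
    """Tidy fluorescence-time observations plus their design context.

    ``observations`` is a DataFrame with columns compound, route, time_h,
    replicate, rfu, censored.  ``regimens`` maps route value → regimen and
    ``compounds`` maps name → record; ``provenance`` records how the data
    came to be (generator settings and seed for synthetic data).
    """

    observations: pd.DataFrame
    regimens: dict[str, ExposureRegimen]
    compounds: dict[str, CompoundRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(DATASET_COLUMNS) - set(self.observations.columns)
        if missing:
            raise ValueError(f"observations missing columns: {sorted(missing)}")
        obs = self.observations
        unknown_c = set(obs["compound"]) - set(self.compounds)
        if unknown_c:
            raise ValueError(f"observations reference unknown compounds: {sorted(unknown_c)}")
        unknown_r = set(obs["route"]) - set(self.regimens)
        if unknown_r:
            raise ValueError(f"observations reference unknown routes: {sorted(unknown_r)}")
        if (obs["rfu"] < 0).any():
            raise ValueError("rfu must be nonnegative")
        if (obs["time_h"] < 0).any():
            raise ValueError("time_h must be nonnegative")

    def for_compound(self, name: str, include_censored: bool = False) -> pd.DataFrame:
        sub = self.observations[self.observations["compound"] == name]
        if name not in self.compounds:
            raise KeyError(f"unknown compound {name!r}")
        if not include_censored:
            sub = sub[~sub["censored"]]
        return sub

    def copy(self) -> "Dataset":
        return Dataset(
            observations=self.observations.copy(),
            regimens=dict(self.regimens),
            compounds=dict(self.compounds),
            provenance=dict(self.provenance),
        )

    # -- CSV round trip -----------------------------------------------
    def write_csv(self, path: "str | Path", sidecar: bool = True) -> None:
        path = Path(path)
        self.observations.to_csv(path, index=False)
        if sidecar:
            meta = {
                "regimens": {k: r.to_dict() for k, r in self.regimens.items()},
                "compounds": {k: asdict(c) for k, c in self.compounds.items()},
                "provenance": self.provenance,
            }
            path.with_suffix(path.suffix + ".meta.json").write_text(
                json.dumps(meta, indent=2, sort_keys=True)
            )


def _substream(seed: int, compound: str, route: str) -> np.random.Generator:
    """Independent RNG substream keyed on (seed, compound, route)."""
    key = (int(seed), zlib.crc32(compound.encode()), zlib.crc32(route.encode()))
    return np.random.default_rng(np.random.SeedSequence(key))


def simulate_dataset(
    truth: Mapping[str, PKParameters],
    compounds: Sequence[CompoundRecord],
    regimens: Sequence[ExposureRegimen],
    n_replicates: int = STUDY_N_REPLICATES,
    noise: NoiseModel | None = None,
    quench: QuenchSpec | None = None,
    seed: int = 0,
) -> Dataset:
    """Simulate a tidy fluorescence-time dataset from known parameters.

    For every (compound, regimen, sampling time, replicate) the expected
    signal ``fluor × A(t)`` is drawn through the noise model; injection
    observations before the quench cutoff are then attenuated.  All
    censoring flags start false — flagging is the fitting stage's job.
    """
    if not regimens:
        raise ValueError("at least one exposure regimen is required")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if noise is None:
        noise = NoiseModel()
    comp_map = {c.name: c for c in compounds}
    missing = set(truth) - set(comp_map)
    if missing:
        raise ValueError(f"truth references compounds without records: {sorted(missing)}")

    frames = []
    for name in truth:
        record = comp_map[name]
        params = truth[name]
        for regimen in regimens:
            rng = _substream(seed, name, regimen.route.value)
            times = np.asarray(regimen.sampling_times_h)
            mean = params.fluor * amount_at_time(params, regimen, times, mw=record.mw)
            t_grid = np.repeat(times, n_replicates)
            mu = np.repeat(mean, n_replicates)
            rfu = mu * noise.draw_factors(rng, mu.size)
            if noise.additive_floor > 0:
                rfu = rfu + noise.additive_floor * rng.standard_normal(mu.size)
            if quench is not None:
                mask = quench.applies(regimen.route, t_grid)
                rfu = np.where(mask, rfu * quench.attenuation, rfu)
            frames.append(pd.DataFrame({
                "compound": name,
                "route": regimen.route.value,
                "time_h": t_grid,
                "replicate": np.tile(np.arange(1, n_replicates + 1), times.size),
                "rfu": np.maximum(rfu, 0.0),
                "censored": False,
            }))

    obs = pd.concat(frames, ignore_index=True)
    provenance = {
        "generator": "zfpk.synthetic_data.simulate_dataset",
        "seed": int(seed),
        "n_replicates": int(n_replicates),
        "noise": {
            "proportional_cv": noise.proportional_cv,
            "additive_floor": noise.additive_floor,
            "distribution": noise.distribution.value,
            "multiplicative_mean": 1.0,  # mean-one convention (not median-one)
        },
        "quench": None if quench is None else {
            "affected_routes": sorted(r.value for r in quench.affected_routes),
            "cutoff_time_h": quench.cutoff_time_h,
            "attenuation": quench.attenuation,
        },
        "truth": {name: truth[name].to_dict() for name in truth},
    }
    return Dataset(
        observations=obs,
        regimens={r.route.value: r for r in regimens},
        compounds={c.name: c for c in comp_map.values()},
        provenance=provenance,
    )


def generate_compound_panel(
    n: int,
    logd_range: tuple[float, float] = (-1.96, 1.73),
    seed: int = 0,
) -> list[CompoundRecord]:
    """Random but plausible compound records for robustness studies.

    LogD uniform over ``logd_range``; MW lognormal around 500 g/mol;
    count descriptors Poisson with panel-typical means.  Deterministic
    per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = logd_range
    if not lo < hi:
        raise ValueError("logd_range must be a nonempty interval")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x9A7E1)))
    logd = rng.uniform(lo, hi, size=n)
    mw = np.exp(rng.normal(np.log(500.0), 0.3, size=n))
    tpsa = rng.uniform(20.0, 260.0, size=n)
    mr = rng.uniform(100.0, 250.0, size=n)
    hba = rng.poisson(5, size=n)
    hbd = rng.poisson(1, size=n)
    rotor = rng.poisson(9, size=n)
    return [
        CompoundRecord(
            name=f"SYN{i + 1:03d}", mw=float(mw[i]), logd=float(logd[i]),
            tpsa=float(tpsa[i]), mr=float(mr[i]), hba=int(hba[i]),
            hbd=int(hbd[i]), rotor=int(rotor[i]), channel="synthetic",
        )
        for i in range(n)
    ]
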