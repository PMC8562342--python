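"""Synthetic fermentation datasets and toy stoichiometric networks.

The simulator emulates a multi-strain wine fermentation with the
statistical structure the downstream analysis assumes:

* logistic biomass growth reaching its maximum by ~120 h from an inoculum
  of OD600 ~0.1;
* sugar (glucose + fructose, 220 g/L total) fermented to < 4 g/L residual
  with ethanol accumulating to ~100 g/L;
* nitrogen compounds depleted with group-structured timing — group I
  (ammonia and the earliest amino acids) 95%-consumed by 28 h, group II by
  44 h, group III by 72 h, and group IV (glycine) only after 96 h after an
  initial delay — while proline is never taken up;
* volatile organic compounds formed as a linear map of nitrogen
  utilizations plus a growth-coupled term, with production plateauing once
  nitrogen is spent and growth stops;
* multiplicative Gaussian measurement noise, truncated at zero.

Consumption kinetics are growth-coupled: the un-consumed fraction of each
nitrogen compound decays exponentially in *integrated biomass*
(a Monod-like, biomass-proportional uptake), with the per-analyte rate
solved so the noise-free trajectory crosses 95% utilization exactly at its
group target time.  The generator's coefficient map (the ground truth
``B_true``) defaults to the qualitative sign structure observed for wine
yeast nitrogen-to-aroma correlations.

Toy networks come with exhaustively computed ground-truth reaction classes
(direct LP enumeration, written against scipy independently of
:mod:`vinoflux.pfba`), so the classification stage is testable end to end
without any external model download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .constraint import MetabolicModel
from .datamodel import NITROGEN_VARIABLES, FermentationDataset, MediumSpec

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "simulate_fermentation",
    "generate_toy_network",
    "TOY_TEMPLATES",
    "DEFAULT_SAMPLE_TIMES",
    "VOC_NAMES",
]

#: Default sampling grid (h): 11 points over a 404-h fermentation.  The
#: early points sit on the nitrogen-group boundary times (28/44/72/96 h)
#: so that interpolated 95%-depletion times respect group membership, and
#: the first five points cover the window of near-complete nitrogen uptake.
DEFAULT_SAMPLE_TIMES = [0.0, 20.0, 28.0, 44.0, 72.0, 96.0, 120.0, 168.0, 240.0, 312.0, 404.0]

VOC_NAMES = [
    "Propan-1-ol",
    "3-Methyl-1-butanol",
    "2-Methylpropan-1-ol",
    "2-Phenylethan-1-ol",
    "Methionol",
    "Ethyl acetate",
    "3-Methylbutyl acetate",
    "2-Methylpropyl acetate",
    "2-Phenylethyl acetate",
    "Ethyl butanoate",
    "Ethyl hexanoate",
]

#: Default qualitative correlation signs of each nitrogen-utilization
#: variable for each volatile (rows: VOC, columns: NITROGEN_VARIABLES).
#: '0' entries correspond to true zero coefficients.
_DEFAULT_SIGNS = {
    #                     NH3  Ala  A/G  Asn  Asp  Glu  Gly  His  Ile  Leu  Lys  Met  Phe  Ser  Thr  Trp  Tyr  Val
    "Propan-1-ol":        " 0    +    -    0    0    -    0    -    +    0    -    -    0    0    +    0    +    0",
    "3-Methyl-1-butanol": " 0    0    -    0    -    -    +    0    0    +    +    0    0    0    0    0    +    0",
    "2-Methylpropan-1-ol":" -    -    0    0    0    -    +    -    0    0    +    -    +    +    -    -    0    0",
    "2-Phenylethan-1-ol": " 0    0    -    0    -    0    +    0    0    0    0    0    0    0    0    0    +    0",
    "Methionol":          " 0    0    -    0    0    0    +    +    0    0    0    -    +    +    0    +    0    -",
    "Ethyl acetate":      " 0    0    -    +    +    -    +    -    +    -    +    -    -    0    0    0    +    -",
    "3-Methylbutyl acetate":" -  0    0    +    +    -    +    +    0    0    0    -    -    -    +    -    +    +",
    "2-Methylpropyl acetate":" 0  0    +    +    +    -    +    -    0    -    +    0    -    +    -    +    +    +",
    "2-Phenylethyl acetate":" 0   0    -    +    0    -    +    0    +    +    +    0    -    -    -    +    +    -",
    "Ethyl butanoate":    " 0    -    0    +    +    -    +    0    0    0    +    0    -    +    -    0    +    +",
    "Ethyl hexanoate":    " 0    0    0    0    0    0    0    0    +    -    -    -    0    0    0    0    +    0",
}

#: Target plateau concentration per VOC (µg/L), within wine-typical ranges.
_VOC_SCALE = {
    "Propan-1-ol": 30_000.0,
    "3-Methyl-1-butanol": 120_000.0,
    "2-Methylpropan-1-ol": 40_000.0,
    "2-Phenylethan-1-ol": 20_000.0,
    "Methionol": 800.0,
    "Ethyl acetate": 50_000.0,
    "3-Methylbutyl acetate": 3_000.0,
    "2-Methylpropyl acetate": 500.0,
    "2-Phenylethyl acetate": 300.0,
    "Ethyl butanoate": 500.0,
    "Ethyl hexanoate": 400.0,
}

#: (initial mg/L, noise-free 95%-depletion target h, uptake-delay h, group).
#: The amino-acid-wise composition of the synthetic must is an assumption
#: (the total, 11 mg/L ammonium within ~123 mg N/L assimilable nitrogen,
#: is the anchored quantity); timing targets respect the group thresholds
#: I <= 28, II <= 44, III <= 72, IV > 96 h with margin for strain jitter.
_DEFAULT_NITROGEN = {
    "NH3": (11.0, 22.0, 0.0, "I"),
    "Asn": (25.0, 25.0, 0.0, "I"),
    "Lys": (15.0, 24.0, 0.0, "I"),
    "Met": (20.0, 25.0, 0.0, "I"),
    "Arg": (280.0, 40.0, 0.0, "II"),
    "Gln": (110.0, 38.0, 0.0, "II"),
    "Glu": (90.0, 39.0, 0.0, "II"),
    "Ile": (25.0, 33.0, 0.0, "II"),
    "Leu": (35.0, 36.0, 0.0, "II"),
    "Phe": (25.0, 38.0, 0.0, "II"),
    "Ser": (60.0, 34.0, 0.0, "II"),
    "Thr": (55.0, 39.0, 0.0, "II"),
    "His": (25.0, 40.0, 0.0, "II"),
    "Asp": (35.0, 32.0, 0.0, "II"),
    "Val": (30.0, 40.0, 0.0, "II"),
    "Ala": (110.0, 58.0, 0.0, "III"),
    "Trp": (70.0, 62.0, 0.0, "III"),
    "Tyr": (15.0, 65.0, 0.0, "III"),
    "Cys": (10.0, 56.0, 0.0, "III"),
    "Gly": (10.0, 108.0, 20.0, "IV"),
    "Pro": (300.0, None, 0.0, None),  # never assimilated
}

_GROUP_LIMITS = {"I": (0.0, 28.0), "II": (28.0, 44.0), "III": (44.0, 72.0)}

_DEFAULT_NOISE_CV = {
    "biomass": 0.03,
    "sugar": 0.02,
    "nitrogen": 0.05,
    "voc": 0.05,
    "metabolite": 0.03,
}

_STRAIN_NAMES = ["Elixir", "Opale", "R2", "Uvaferm"]


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic fermentation."""

    n_strains: int = 4
    n_replicates: int = 3
    sample_times_h: list[float] = field(
        default_factory=lambda: list(DEFAULT_SAMPLE_TIMES)
    )
    # logistic growth (gDW/L, /h, h)
    x_max: float = 2.5
    mu_max: float = 0.08
    lag_h: float = 5.0
    x0: float = 0.05
    # sugars (g/L)
    sugar_initial: dict[str, float] = field(
        default_factory=lambda: {"glucose": 110.0, "fructose": 110.0}
    )
    sugar_residual: float = 4.0
    ethanol_yield: float = 0.44  # g ethanol / g sugar
    nitrogen: dict[str, tuple] = field(
        default_factory=lambda: dict(_DEFAULT_NITROGEN)
    )
    voc_signs: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_SIGNS))
    voc_growth_frac: float = 0.02  # growth-coupled share of the VOC plateau
    noise_cv: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_NOISE_CV)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        t_max = max(self.sample_times_h)
        for analyte, (c0, t95, delay, group) in self.nitrogen.items():
            if c0 < 0:
                raise ValueError(f"negative initial concentration for {analyte!r}")
            if t95 is None:
                continue
            if not delay < t95 < t_max:
                raise ValueError(
                    f"{analyte!r}: depletion target {t95} h incompatible with "
                    f"the sample grid (0..{t_max} h)"
                )
            if group in _GROUP_LIMITS:
                lo, hi = _GROUP_LIMITS[group]
                if not lo < t95 <= hi:
                    raise ValueError(
                        f"{analyte!r}: target {t95} h outside group {group} "
                        f"window ({lo}, {hi}]"
                    )
            elif group == "IV" and t95 <= 96.0:
                raise ValueError(f"{analyte!r}: group IV requires target > 96 h")
        for cls, cv in self.noise_cv.items():
            if cv < 0:
                raise ValueError(f"negative noise CV for class {cls!r}")


@dataclass
class GroundTruth:
    """Generation-time truth for recovery tests.

    For fermentations: the true linear map utilization -> VOC and the
    growth-term coefficients.  For toy networks: the reaction classes and
    the essential set.
    """

    voc_coefficients: pd.DataFrame | None = None
    growth_coefficients: dict[str, float] | None = None
    reaction_classes: dict[str, str] | None = None
    essential_set: set[str] | None = None

    def to_json(self, path: str | Path) -> None:
        payload: dict = {}
        if self.voc_coefficients is not None:
            payload["voc_coefficients"] = {
                "index": list(self.voc_coefficients.index),
                "columns": list(self.voc_coefficients.columns),
                "values": self.voc_coefficients.to_numpy().tolist(),
            }
        if self.growth_coefficients is not None:
            payload["growth_coefficients"] = self.growth_coefficients
        if self.reaction_classes is not None:
            payload["reaction_classes"] = self.reaction_classes
        if self.essential_set is not None:
            payload["essential_set"] = sorted(self.essential_set)
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        voc = None
        if "voc_coefficients" in payload:
            blk = payload["voc_coefficients"]
            voc = pd.DataFrame(
                blk["values"], index=blk["index"], columns=blk["columns"]
            )
        return cls(
            voc_coefficients=voc,
            growth_coefficients=payload.get("growth_coefficients"),
            reaction_classes=payload.get("reaction_classes"),
            essential_set=set(payload["essential_set"])
            if "essential_set" in payload
            else None,
        )


# -- fermentation kinetics -------------------------------------------------

def _biomass(t: np.ndarray, spec: SimulationSpec) -> np.ndarray:
    """Logistic growth with a lag phase."""
    tau = np.clip(np.asarray(t, dtype=float) - spec.lag_h, 0.0, None)
    K, X0 = spec.x_max, spec.x0
    e = np.exp(spec.mu_max * tau)
    return K * X0 * e / (K - X0 + X0 * e)


def _biomass_integral(t: np.ndarray, spec: SimulationSpec) -> np.ndarray:
    """Closed-form integral of the logistic curve (gDW h / L)."""
    t = np.asarray(t, dtype=float)
    tau = np.clip(t - spec.lag_h, 0.0, None)
    K, X0, mu = spec.x_max, spec.x0, spec.mu_max
    pre = X0 * np.minimum(t, spec.lag_h)
    post = (K / mu) * np.log((K - X0 + X0 * np.exp(mu * tau)) / K)
    return pre + post


def _uptake_fraction(
    t: np.ndarray,
    t95: float | None,
    delay: float,
    spec: SimulationSpec,
    shape: float = 1.0,
    early_fraction: float = 0.0,
    early_shape: float | None = None,
) -> np.ndarray:
    """Fraction of the initial pool consumed by time t (noise-free).

    Monod-like, biomass-coupled depletion: the un-consumed fraction decays
    as ``exp(-k * G^h)`` in integrated biomass G past the uptake delay.
    The per-analyte shape exponent h captures transporter-affinity and
    repression/derepression differences between compounds and strains.
    ``early_fraction`` > 0 makes uptake biphasic — a partial early phase
    (catabolite-derepression style) ahead of the bulk phase.  In every
    case the rate of the bulk phase is solved so the combined noise-free
    curve crosses 95% utilization exactly at ``t95``.
    """
    t = np.asarray(t, dtype=float)
    if t95 is None:
        return np.zeros_like(t)
    g = _biomass_integral(t, spec)
    g_delay = _biomass_integral(np.array([delay]), spec)[0]
    gd = np.clip(g - g_delay, 0.0, None)

    def gd_at(tt: float) -> float:
        return max(
            _biomass_integral(np.array([tt]), spec)[0] - g_delay, 1e-12
        )

    gd95 = gd_at(t95)
    if early_fraction <= 0.0:
        k = np.log(20.0) / gd95**shape  # ln 20: 95% consumed
        return 1.0 - np.exp(-k * gd**shape)
    # biphasic: an early partial phase (its own 95% point at 0.4 * t95)
    # plus the bulk phase, whose rate is solved so the combined curve still
    # crosses 95% exactly at t95
    h2 = early_shape if early_shape is not None else shape
    k1 = np.log(20.0) / gd_at(0.4 * t95) ** h2
    u1 = 1.0 - np.exp(-k1 * gd**h2)
    u1_t95 = 1.0 - np.exp(-k1 * gd95**h2)
    f = early_fraction
    rhs = (0.05 - f * (1.0 - u1_t95)) / (1.0 - f)
    rhs = min(max(rhs, 1e-9), 1.0 - 1e-9)
    k2 = -np.log(rhs) / gd95**shape
    u2 = 1.0 - np.exp(-k2 * gd**shape)
    return f * u1 + (1.0 - f) * u2


def _build_coefficients(
    spec: SimulationSpec, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Draw the true utilization->VOC linear map.

    Each variable's full-depletion contribution to a VOC is comparable in
    size (coefficients scale inversely with the initial pool), positives
    dominate negatives, and negatives are shrunk deterministically until no
    noise-free trajectory goes below zero.
    """
    pools = {a: v[0] for a, v in spec.nitrogen.items()}
    pools["Arg/Gln"] = pools.get("Arg", 0.0) + pools.get("Gln", 0.0)
    cols = list(NITROGEN_VARIABLES)
    vocs = list(spec.voc_signs)
    B = pd.DataFrame(0.0, index=vocs, columns=cols)
    growth_c: dict[str, float] = {}
    for voc in vocs:
        signs = spec.voc_signs[voc].split()
        if len(signs) != len(cols):
            raise ValueError(f"sign row for {voc!r} has {len(signs)} entries")
        n_pos = max(signs.count("+"), 1)
        amp = _VOC_SCALE[voc] / n_pos
        for s, col in zip(signs, cols):
            if s == "0":
                continue
            mag = amp * rng.uniform(1.0, 1.6)
            if s == "-":
                mag *= -1.0
            B.loc[voc, col] = mag / max(pools[col], 1e-9)
        growth_c[voc] = spec.voc_growth_frac * _VOC_SCALE[voc] / spec.x_max
    return B, growth_c


def _noisy(
    values: np.ndarray, cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Multiplicative Gaussian noise truncated at zero.

    The first element (the t = 0 sample) is left exact: in a defined
    synthetic must the initial composition is the formulation itself, so
    measurement error applies to samples drawn after inoculation.
    """
    if cv == 0:
        return values
    noisy = np.clip(
        values * (1.0 + cv * rng.standard_normal(values.shape)), 0.0, None
    )
    noisy[0] = values[0]
    return noisy


def simulate_fermentation(
    spec: SimulationSpec | None = None,
) -> tuple[FermentationDataset, GroundTruth]:
    """Generate a multi-strain fermentation dataset plus its ground truth.

    Identical spec (including seed) gives bit-identical output.  Strains
    differ through small seeded jitter on nitrogen depletion timing (within
    +-4%, so group membership is preserved) and through the replicate-level
    measurement noise.
    """
    spec = spec or SimulationSpec()
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(sorted(spec.sample_times_h), dtype=float)
    if times[0] != 0:
        raise ValueError("the sample grid must include time 0")

    B_true, growth_c = _build_coefficients(spec, rng)
    strains = (_STRAIN_NAMES + [f"S{i}" for i in range(5, spec.n_strains + 1)])[
        : spec.n_strains
    ]
    # Strain- and replicate-level kinetic diversity, drawn up front so
    # iteration order stays deterministic.  Timing jitter is bounded so the
    # combined strain x replicate factor stays within +-10% of the group
    # target and group membership is preserved; uptake-shape exponents vary
    # per strain and replicate (biological replicates of a fermentation
    # genuinely differ in uptake kinetics, and that variation carries into
    # the volatiles through the true coefficient map).
    strain_jit = {
        (s, a): rng.uniform(0.93, 1.07) for s in strains for a in spec.nitrogen
    }
    strain_shape = {
        (s, a): rng.uniform(0.45, 2.1) for s in strains for a in spec.nitrogen
    }
    strain_early_frac = {
        (s, a): rng.uniform(0.0, 0.5) for s in strains for a in spec.nitrogen
    }
    strain_early_shape = {
        (s, a): rng.uniform(0.45, 2.1) for s in strains for a in spec.nitrogen
    }
    strain_delay = {
        (s, a): (
            spec.nitrogen[a][2]
            if spec.nitrogen[a][2] > 0
            else rng.uniform(0.0, 4.0 if spec.nitrogen[a][3] == "I" else 10.0)
        )
        for s in strains
        for a in spec.nitrogen
    }
    rep_jit = {
        (s, r, a): rng.uniform(0.98, 1.02)
        for s in strains
        for r in range(1, spec.n_replicates + 1)
        for a in spec.nitrogen
    }
    rep_shape = {
        (s, r, a): np.clip(strain_shape[s, a] * rng.uniform(0.85, 1.15), 0.4, 2.4)
        for s in strains
        for r in range(1, spec.n_replicates + 1)
        for a in spec.nitrogen
    }
    rep_early_frac = {
        (s, r, a): float(np.clip(strain_early_frac[s, a] + rng.uniform(-0.08, 0.08), 0.0, 0.55))
        for s in strains
        for r in range(1, spec.n_replicates + 1)
        for a in spec.nitrogen
    }

    s0_total = sum(spec.sugar_initial.values())
    g_end = _biomass_integral(times[-1:], spec)[0]
    ks = -np.log(0.01) / g_end  # 99% of fermentable sugar gone by the end

    # pass 1: noise-free trajectories per (strain, replicate)
    biomass_tracks: dict[tuple[str, int], np.ndarray] = {}
    util_tracks: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for strain in strains:
        for rep in range(1, spec.n_replicates + 1):
            biomass_tracks[strain, rep] = _biomass(times, spec)
            util: dict[str, np.ndarray] = {}
            for analyte, (c0, t95, delay, _) in spec.nitrogen.items():
                t95_eff = (
                    None
                    if t95 is None
                    else t95
                    * strain_jit[strain, analyte]
                    * rep_jit[strain, rep, analyte]
                )
                util[analyte] = c0 * _uptake_fraction(
                    times,
                    t95_eff,
                    strain_delay[strain, analyte],
                    spec,
                    shape=rep_shape[strain, rep, analyte],
                    early_fraction=rep_early_frac[strain, rep, analyte],
                    early_shape=strain_early_shape[strain, analyte],
                )
            merged = dict(util)
            merged["Arg/Gln"] = merged.pop("Arg", 0.0) + merged.pop("Gln", 0.0)
            util_tracks[strain, rep] = merged

    # keep every noise-free VOC trajectory non-negative WITHOUT clipping,
    # so the emitted data follow the *returned* B_true exactly: first try
    # shrinking the negative coefficients (never below half their drawn
    # size, or they become statistically invisible); if that is not enough,
    # raise the VOC's growth-coupled term until the dips are covered
    for voc in B_true.index:
        neg_cols = [c for c in B_true.columns if B_true.loc[voc, c] < 0]
        if not neg_cols:
            continue

        def trajectory_parts(g: float, nf: float):
            worst_ratio, g_req = np.inf, 0.0
            for (strain, rep), merged in util_tracks.items():
                growth = biomass_tracks[strain, rep] - spec.x0
                pos = g * growth + sum(
                    B_true.loc[voc, c] * merged[c]
                    for c in B_true.columns
                    if B_true.loc[voc, c] > 0
                )
                neg = nf * sum(
                    B_true.loc[voc, c] * merged[c] for c in neg_cols
                )
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = np.where(neg < 0, pos / -neg, np.inf)
                    need = np.where(
                        (pos + neg < 0) & (growth > 1e-6),
                        -(pos + neg) / growth,
                        0.0,
                    )
                worst_ratio = min(worst_ratio, float(np.min(ratio)))
                g_req = max(g_req, float(np.max(need)))
            return worst_ratio, g_req

        factor, _ = trajectory_parts(growth_c[voc], 1.0)
        if factor < 1.0:
            B_true.loc[voc, neg_cols] *= max(factor, 0.0)

    rows: list[tuple] = []

    def emit(strain, rep, analyte, values, unit, cv_class):
        cv = spec.noise_cv.get(cv_class, 0.0)
        noisy = _noisy(values, cv, rng)
        if cv_class == "voc":
            # the volatile assay runs technical duplicates; report the mean
            noisy = 0.5 * (noisy + _noisy(values, cv, rng))
        for t, v in zip(times, noisy):
            rows.append((strain, rep, float(t), analyte, float(v), unit))

    # pass 2: emit observed (noisy) records
    for strain in strains:
        for rep in range(1, spec.n_replicates + 1):
            X = biomass_tracks[strain, rep]
            emit(strain, rep, "biomass", X, "gDW/L", "biomass")

            frac_left = np.exp(-ks * _biomass_integral(times, spec))
            total_sugar = np.zeros_like(times)
            for sugar, c0 in spec.sugar_initial.items():
                speed = {"glucose": 1.15, "fructose": 0.90}.get(sugar, 1.0)
                s_t = c0 * frac_left**speed
                total_sugar += s_t
                emit(strain, rep, sugar, s_t, "g/L", "sugar")
            emit(
                strain, rep, "ethanol",
                spec.ethanol_yield * (s0_total - total_sugar), "g/L", "sugar",
            )
            emit(strain, rep, "brix", total_sugar / 10.0, "Brix", "sugar")

            merged = util_tracks[strain, rep]
            for analyte, (c0, _, _, _) in spec.nitrogen.items():
                key = "Arg/Gln" if analyte in ("Arg", "Gln") else analyte
                if analyte in ("Arg", "Gln"):
                    # split the merged pool back proportionally to C0
                    share = c0 / (
                        spec.nitrogen["Arg"][0] + spec.nitrogen["Gln"][0]
                    )
                    u = merged[key] * share
                else:
                    u = merged[key]
                emit(strain, rep, analyte, c0 - u, "mg/L", "nitrogen")

            for voc in B_true.index:
                y = growth_c[voc] * (X - spec.x0)
                for col in B_true.columns:
                    y = y + B_true.loc[voc, col] * merged[col]
                y = np.clip(y, 0.0, None)  # guard; shrink keeps y >= 0
                emit(strain, rep, voc, y, "µg/L", "voc")

    records = pd.DataFrame(
        rows, columns=["strain", "replicate", "time_h", "analyte", "value", "unit"]
    )
    medium = MediumSpec(
        sugars=dict(spec.sugar_initial),
        yan_mg_per_L=123.0,
        ammonium_mg_per_L=spec.nitrogen.get("NH3", (0.0,))[0],
        amino_acids={
            a: v[0] for a, v in spec.nitrogen.items() if a != "NH3"
        },
    )
    ds = FermentationDataset(records, medium=medium, assay_corrected={"NH3"})
    truth = GroundTruth(voc_coefficients=B_true, growth_coefficients=growth_c)
    return ds, truth


# -- toy stoichiometric networks ------------------------------------------

TOY_TEMPLATES = (
    "chain",
    "parallel_equal_yield",
    "suboptimal_branch",
    "ehrlich_motif",
    "random",
)


def _model_from_rows(
    rows: list[tuple[str, str, float, float, bool, str]], biomass: str
) -> MetabolicModel:
    """rows: (id, equation, lb, ub, gene_associated, subsystem)."""
    from .constraint import _parse_equation

    met_order: list[str] = []
    met_pos: dict[str, int] = {}
    parsed = []
    for i, (rid, eq, lb, ub, gene, sub) in enumerate(rows):
        terms, _ = _parse_equation(eq, i + 1)
        for _, m in terms:
            if m not in met_pos:
                met_pos[m] = len(met_order)
                met_order.append(m)
        parsed.append(terms)
    S = np.zeros((len(met_order), len(rows)))
    for j, terms in enumerate(parsed):
        for c, m in terms:
            S[met_pos[m], j] += c
    model = MetabolicModel(
        metabolites=met_order,
        reactions=[r[0] for r in rows],
        S=S,
        lb=np.array([r[2] for r in rows], float),
        ub=np.array([r[3] for r in rows], float),
        gene_associated=np.array([r[4] for r in rows], bool),
        subsystem=[r[5] for r in rows],
        biomass_rxn=biomass,
    )
    model.exchange_rxns = model.infer_exchanges()
    return model


def _chain(n: int) -> MetabolicModel:
    rows = [("EX_M0", "M0 ->", -10.0, 1000.0, False, "exchange")]
    for i in range(n):
        rows.append(
            (f"R{i + 1}", f"M{i} -> M{i + 1}", 0.0, 1000.0, True, "chain")
        )
    rows.append(("BIOMASS", f"M{n} ->", 0.0, 1000.0, False, "biomass"))
    return _model_from_rows(rows, "BIOMASS")


def _parallel_equal_yield() -> MetabolicModel:
    rows = [
        ("EX_A", "A ->", -10.0, 1000.0, False, "exchange"),
        ("SHORT", "A -> B", 0.0, 1000.0, True, "short path"),
        ("LONG1", "A -> C", 0.0, 1000.0, True, "long path"),
        ("LONG2", "C -> B", 0.0, 1000.0, True, "long path"),
        ("BIOMASS", "B ->", 0.0, 1000.0, False, "biomass"),
    ]
    return _model_from_rows(rows, "BIOMASS")


def _suboptimal_branch() -> MetabolicModel:
    rows = [
        ("EX_A", "A ->", -10.0, 1000.0, False, "exchange"),
        ("R1", "A -> B", 0.0, 1000.0, True, "core"),
        ("DIVERT", "B -> D", 0.0, 1000.0, True, "overflow"),
        ("EX_D", "D ->", 0.0, 1000.0, False, "exchange"),
        ("EX_E", "E ->", 0.0, 1000.0, False, "exchange"),
        ("R3", "E -> B", 0.0, 1000.0, True, "salvage"),
        ("ORPHAN", "Z -> W", 0.0, 1000.0, True, "disconnected"),
        ("BIOMASS", "B ->", 0.0, 1000.0, False, "biomass"),
    ]
    return _model_from_rows(rows, "BIOMASS")


def _ehrlich_motif() -> MetabolicModel:
    """Uptake -> transaminase -> decarboxylase -> reduction ->
    (secretion | esterification) chain with a growth-coupled nitrogen drain.

    Biomass requires both a carbon precursor P and glutamate; glutamate is
    made only by transamination of the imported amino acid, so the Ehrlich
    entry reactions are structurally growth-coupled.
    """
    rows = [
        ("EX_glucose", "glucose ->", -10.0, 1000.0, False, "exchange"),
        ("EX_Leu", "Leu_e ->", -2.0, 1000.0, False, "exchange"),
        ("LEUt", "Leu_e -> Leu", 0.0, 1000.0, True, "amino acid transport"),
        ("GLYC", "glucose -> 2 P", 0.0, 1000.0, True, "glycolysis"),
        ("AKGS", "P -> AKG", 0.0, 1000.0, True, "glutamate metabolism"),
        ("TA", "Leu + AKG -> KA + Glu_m", 0.0, 1000.0, True,
         "amino acid metabolism"),
        ("KADC", "KA -> AL", 0.0, 1000.0, True, "complex alcohol metabolism"),
        ("ALR", "AL -> FOL", 0.0, 1000.0, True, "complex alcohol metabolism"),
        ("ACS", "P -> ACX", 0.0, 1000.0, True, "pyruvate metabolism"),
        ("ATF", "FOL + ACX -> EST", 0.0, 1000.0, True, "ester synthesis"),
        ("FERM", "P -> 1.5 EtOH", 0.0, 1000.0, True, "fermentation"),
        ("EX_EtOH", "EtOH ->", 0.0, 1000.0, False, "exchange"),
        ("EX_FOL", "FOL ->", 0.0, 1000.0, False, "exchange"),
        ("EX_EST", "EST ->", 0.0, 1000.0, False, "exchange"),
        ("BIOMASS", "P + 0.2 Glu_m ->", 0.0, 1000.0, False, "biomass"),
    ]
    return _model_from_rows(rows, "BIOMASS")


def _random_network(rng: np.random.Generator, n_internal: int) -> MetabolicModel:
    """Random layered network: one substrate exchange, a chain backbone
    guaranteeing growth, plus random cross reactions."""
    n_mets = max(3, n_internal)
    mets = [f"X{i}" for i in range(n_mets)]
    rows = [("EX_X0", "X0 ->", -10.0, 1000.0, False, "exchange")]
    # backbone
    backbone = rng.choice(np.arange(1, n_mets), size=min(3, n_mets - 1), replace=False)
    path = [0] + sorted(int(i) for i in backbone)
    for a, b in zip(path[:-1], path[1:]):
        rows.append(
            (f"B{a}_{b}", f"{mets[a]} -> {mets[b]}", 0.0, 1000.0, True, "backbone")
        )
    target = path[-1]
    for _ in range(n_internal):
        i, j = rng.integers(0, n_mets, size=2)
        if i == j:
            continue
        rid = f"R{len(rows)}"
        coeff = rng.choice([1.0, 1.0, 2.0])
        rev = rng.random() < 0.3
        arrow = "<=>" if rev else "->"
        rows.append(
            (
                rid,
                f"{mets[int(i)]} {arrow} {coeff:g} {mets[int(j)]}",
                -1000.0 if rev else 0.0,
                1000.0,
                bool(rng.random() < 0.8),
                rng.choice(["core", "peripheral", "overflow"]),
            )
        )
    if rng.random() < 0.5:  # secondary secretion
        k = int(rng.integers(1, n_mets))
        rows.append((f"EX_X{k}", f"X{k} ->", 0.0, 1000.0, False, "exchange"))
    rows.append(("BIOMASS", f"{mets[target]} ->", 0.0, 1000.0, False, "biomass"))
    # deduplicate reaction ids
    seen: set[str] = set()
    unique = []
    for row in rows:
        if row[0] in seen:
            continue
        seen.add(row[0])
        unique.append(row)
    return _model_from_rows(unique, "BIOMASS")


def generate_toy_network(
    template: str,
    size: int = 3,
    seed: int | None = None,
    max_attempts: int = 50,
) -> tuple[MetabolicModel, GroundTruth]:
    """Build a toy model with exhaustively enumerated ground-truth classes.

    ``size`` is the internal-chain length for ``chain`` and the number of
    random internal reactions for ``random``; other templates are fixed.
    """
    if template not in TOY_TEMPLATES:
        raise ValueError(f"unknown template {template!r}; one of {TOY_TEMPLATES}")
    if template == "chain":
        model = _chain(size)
    elif template == "parallel_equal_yield":
        model = _parallel_equal_yield()
    elif template == "suboptimal_branch":
        model = _suboptimal_branch()
    elif template == "ehrlich_motif":
        model = _ehrlich_motif()
    else:
        rng = np.random.default_rng(seed)
        model = None
        for _ in range(max_attempts):
            cand = _random_network(rng, size)
            if _oracle_growth(cand) > 1e-6:
                model = cand
                break
        if model is None:
            raise RuntimeError(
                f"no random model with positive growth in {max_attempts} attempts"
            )
    classes = oracle_classify(model)
    truth = GroundTruth(
        reaction_classes=classes,
        essential_set={r for r, c in classes.items() if c == "essential"},
    )
    return model, truth


# -- independent brute-force classifier (generation-time oracle) ----------
#
# Written directly against scipy.optimize.linprog, sharing no code with
# vinoflux.pfba, so generated ground truth and the classification stage
# form two independent routes to the same answer.

def _olp(c, A_eq, lb, ub, sense, A_ub=None, b_ub=None):
    res = linprog(
        np.asarray(c) * (-1.0 if sense == "max" else 1.0),
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status != 0:
        return None
    return (res.fun * (-1.0 if sense == "max" else 1.0), res.x)


def _oracle_growth(model: MetabolicModel, knockout: int | None = None) -> float:
    lb, ub = model.lb.copy(), model.ub.copy()
    if knockout is not None:
        lb[knockout] = ub[knockout] = 0.0
    c = np.zeros(len(model.reactions))
    c[model.rxn_index(model.biomass_rxn)] = 1.0
    out = _olp(c, model.S, lb, ub, "max")
    return out[0] if out else 0.0


def _oracle_can_carry(
    model: MetabolicModel,
    j: int,
    lb: np.ndarray,
    ub: np.ndarray,
    min_growth: float | None = None,
    gene_budget: float | None = None,
    tol: float = 1e-9,
) -> bool:
    """Can reaction j carry nonzero flux under the given conditions?"""
    n = len(model.reactions)
    gene_idx = np.flatnonzero(model.gene_associated)
    k = gene_idx.size if gene_budget is not None else 0
    A_eq = model.S if k == 0 else np.hstack([model.S, np.zeros((model.S.shape[0], k))])
    LB = np.concatenate([lb, np.zeros(k)])
    UB = np.concatenate([ub, np.full(k, 1000.0)])
    A_ub_rows, b_ub = [], []
    if min_growth is not None:
        row = np.zeros(n + k)
        row[model.rxn_index(model.biomass_rxn)] = -1.0
        A_ub_rows.append(row)
        b_ub.append(-min_growth)
    if gene_budget is not None:
        for i, g in enumerate(gene_idx):
            r1 = np.zeros(n + k)
            r1[g], r1[n + i] = 1.0, -1.0
            r2 = np.zeros(n + k)
            r2[g], r2[n + i] = -1.0, -1.0
            A_ub_rows += [r1, r2]
            b_ub += [0.0, 0.0]
        bud = np.zeros(n + k)
        bud[n:] = 1.0
        A_ub_rows.append(bud)
        b_ub.append(gene_budget)
    A_ub = np.vstack(A_ub_rows) if A_ub_rows else None
    bu = np.asarray(b_ub) if b_ub else None
    c = np.zeros(n + k)
    c[j] = 1.0
    hi = _olp(c, A_eq, LB, UB, "max", A_ub, bu)
    lo = _olp(c, A_eq, LB, UB, "min", A_ub, bu)
    if hi is None or lo is None:
        raise RuntimeError("oracle LP failed")
    return hi[0] > tol or lo[0] < -tol


def _oracle_min_gene_flux(model: MetabolicModel, min_growth: float) -> float:
    n = len(model.reactions)
    gene_idx = np.flatnonzero(model.gene_associated)
    k = gene_idx.size
    A_eq = np.hstack([model.S, np.zeros((model.S.shape[0], k))])
    LB = np.concatenate([model.lb, np.zeros(k)])
    UB = np.concatenate([model.ub, np.full(k, 1000.0)])
    rows, rhs = [], []
    g_row = np.zeros(n + k)
    g_row[model.rxn_index(model.biomass_rxn)] = -1.0
    rows.append(g_row)
    rhs.append(-min_growth)
    for i, g in enumerate(gene_idx):
        r1 = np.zeros(n + k)
        r1[g], r1[n + i] = 1.0, -1.0
        r2 = np.zeros(n + k)
        r2[g], r2[n + i] = -1.0, -1.0
        rows += [r1, r2]
        rhs += [0.0, 0.0]
    c = np.zeros(n + k)
    c[n:] = 1.0
    out = _olp(c, A_eq, LB, UB, "min", np.vstack(rows), np.asarray(rhs))
    if out is None:
        raise RuntimeError("oracle parsimonious LP failed")
    return out[0]


def oracle_classify(
    model: MetabolicModel, eps_growth: float = 1e-6, tol: float = 1e-9
) -> dict[str, str]:
    """Exhaustive per-reaction classification by direct LP enumeration."""
    g_star = _oracle_growth(model)
    if g_star <= 0:
        raise RuntimeError("oracle requires positive wildtype growth")
    open_lb, open_ub = model.lb.copy(), model.ub.copy()
    for r in model.exchange_rxns:
        j = model.rxn_index(r)
        open_lb[j], open_ub[j] = -1000.0, 1000.0
    min_growth = g_star * (1 - 1e-9)
    min_flux = _oracle_min_gene_flux(model, min_growth)
    budget = min_flux * (1 + 1e-9) + tol
    # constraints with relative slack admit fluxes up to that slack; the
    # "carries flux" threshold under them must dominate it
    slack_tol = tol + 100.0 * 1e-9 * max(abs(g_star), min_flux, 1.0)

    classes: dict[str, str] = {}
    for j, r in enumerate(model.reactions):
        if not _oracle_can_carry(model, j, open_lb, open_ub, tol=tol):
            classes[r] = "blocked"
        elif _oracle_growth(model, knockout=j) < eps_growth:
            classes[r] = "essential"
        elif not _oracle_can_carry(model, j, model.lb, model.ub, tol=tol):
            classes[r] = "no_flux"
        elif not _oracle_can_carry(
            model, j, model.lb, model.ub, min_growth=min_growth, tol=slack_tol
        ):
            classes[r] = "MLE"
        elif _oracle_can_carry(
            model, j, model.lb, model.ub,
            min_growth=min_growth, gene_budget=budget, tol=slack_tol,
        ):
            classes[r] = "pfba_optima"
        else:
            classes[r] = "ELE"
    return classes
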