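"""Synthetic two-group circadian metabolome generator with known ground truth.

Each metabolite is generated from a cosine model

    y(t) = M + A * cos(2*pi*(t - phi)/period) + eps

sampled on the study grid (two groups x ZT {0, 6, 12, 18} x 4 replicates by
default).  LD samples come from the base parameters; LL samples from the
parameters modified by a per-metabolite group effect (acrophase + delay mod
period, amplitude x scale, mesor + shift).  Defaults emulate the study
conditions: 398 metabolites of which 58 are rhythmic in LD; 8 of those carry
a +6.4 h phase delay with 21% amplitude damping in LL; 33 more lose their
rhythm entirely in LL (58 -> 25), chosen night-peaked-first so the nocturnal
peak-dominated acrophase distribution (56.9% of rhythmic metabolites peaking
in ZT 12-24) collapses under LL; 39 flat metabolites carry a global 1.5-fold
abundance effect.

Noise: sigma = 0.25*A for rhythmic metabolites and 0.10*M for flat ones --
the study reports no abundance variances, so these are the package's
calibration, documented in the methods note.  One RNG stream is spawned per
metabolite from the master seed, so enlarging the panel never perturbs
existing metabolites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataio import MetaboliteTable
from .rhythms import wrap_phase

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RhythmSpec:
    """Generating parameters of one metabolite in the reference group."""
    mesor: float
    amplitude: float
    acrophase: float
    period: float = 24.0
    sigma: float = 0.0
    rhythmic: bool = True

    def __post_init__(self) -> None:
        if not self.rhythmic and self.amplitude != 0:
            raise ValueError("arrhythmic spec must have amplitude 0")
        if self.amplitude < 0 or self.sigma < 0:
            raise ValueError("amplitude and sigma must be non-negative")

    def evaluate(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        return self.mesor + self.amplitude * np.cos(
            2 * np.pi * (t - self.acrophase) / self.period)


@dataclass(frozen=True)
class GroupEffect:
    """Treatment-group modification of a RhythmSpec."""
    phase_delay: float = 0.0
    amplitude_scale: float = 1.0
    mesor_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_scale < 0:
            raise ValueError("amplitude_scale must be >= 0")

    def apply(self, spec: RhythmSpec) -> RhythmSpec:
        amp = spec.amplitude * self.amplitude_scale
        return replace(spec,
                       mesor=spec.mesor + self.mesor_shift,
                       amplitude=amp,
                       acrophase=(spec.acrophase + self.phase_delay) % spec.period,
                       rhythmic=spec.rhythmic and amp > 0)


@dataclass
class GeneratorConfig:
    """Study-design parameters of the generator (defaults = study conditions)."""
    n_metabolites: int = 398
    frac_rhythmic: float = 58 / 398
    frac_disrupted_given_rhythmic: float = 8 / 58
    frac_abolished_given_rhythmic: float = 33 / 58
    n_fc_effects: int = 39
    fc_effect_size: float = 1.5
    replicates_per_cell: int = 4
    timepoints: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0)
    period: float = 24.0
    seed: int = 0
    noise_model: str = "gaussian"          # or "lognormal"
    rel_amplitude_range: tuple[float, float] = (0.3, 0.6)
    noise_to_amplitude: float = 0.25       # sigma = 0.25 * A (rhythmic)
    arrhythmic_noise_frac: float = 0.10    # sigma = 0.10 * mesor (flat)
    nocturnal_fraction: float = 0.569      # P(acrophase in dark phase)
    nocturnal_loss_bias: bool = True       # abolish night-peaked rhythms first
    disrupted_phase_delay: float = 6.4
    disrupted_amplitude_scale: float = 0.79

    def __post_init__(self) -> None:
        if self.n_metabolites <= 0 or self.replicates_per_cell <= 0:
            raise ValueError("counts must be positive")
        for name in ("frac_rhythmic", "frac_disrupted_given_rhythmic",
                     "frac_abolished_given_rhythmic", "nocturnal_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if len(self.timepoints) == 0:
            raise ValueError("timepoint list must not be empty")
        if self.noise_model not in ("gaussian", "lognormal"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass
class GroundTruth:
    """Per-metabolite generating parameters, roles and derived true effects."""
    table: pd.DataFrame  # indexed by metabolite_id
    config: GeneratorConfig

    @property
    def rhythmic_ids(self) -> list[str]:
        return list(self.table.index[self.table["rhythmic"]])

    @property
    def disrupted_ids(self) -> list[str]:
        return list(self.table.index[self.table["role"] == "core_disrupted"])

    @property
    def abolished_ids(self) -> list[str]:
        return list(self.table.index[self.table["role"] == "abolished"])

    @property
    def ll_rhythmic_ids(self) -> list[str]:
        return list(self.table.index[self.table["ll_rhythmic"]])

    @property
    def fc_effect_ids(self) -> list[str]:
        return list(self.table.index[self.table["role"] == "fc_effect"])


def _draw_base_spec(rng: np.random.Generator, rhythmic: bool,
                    gcfg: GeneratorConfig) -> RhythmSpec:
    mesor = float(rng.lognormal(mean=np.log(100.0), sigma=0.4))
    if not rhythmic:
        return RhythmSpec(mesor, 0.0, 0.0, gcfg.period,
                          sigma=gcfg.arrhythmic_noise_frac * mesor, rhythmic=False)
    rel = float(rng.uniform(*gcfg.rel_amplitude_range))
    amp = rel * mesor
    half = gcfg.period / 2
    if rng.random() < gcfg.nocturnal_fraction:
        acro = float(rng.uniform(half, gcfg.period))   # dark phase
    else:
        acro = float(rng.uniform(0.0, half))           # light phase
    return RhythmSpec(mesor, amp, acro, gcfg.period,
                      sigma=gcfg.noise_to_amplitude * amp, rhythmic=True)


def _sample_series(spec: RhythmSpec, t: np.ndarray, rng: np.random.Generator,
                   noise_model: str) -> tuple[np.ndarray, int]:
    signal = spec.evaluate(t)
    if spec.sigma == 0:
        return signal, 0
    if noise_model == "gaussian":
        y = signal + rng.normal(0.0, spec.sigma, size=t.size)
        clipped = int((y < 0).sum())
        return np.clip(y, 0.0, None), clipped
    # lognormal: multiplicative noise on the log scale with a CV matching
    # sigma/mesor, keeping values strictly positive
    sigma_log = spec.sigma / max(spec.mesor, 1e-12)
    return signal * np.exp(rng.normal(0.0, sigma_log, size=t.size)), 0


def generate_dataset(gcfg: GeneratorConfig) -> tuple[MetaboliteTable, GroundTruth]:
    """Generate the two-group dataset and its ground truth.

    Deterministic in ``gcfg.seed``; roles are assigned by metabolite index
    (counts exactly match the configured fractions) and all random parameter
    draws come from per-metabolite spawned streams.
    """
    n = gcfg.n_metabolites
    n_rhythmic = round(gcfg.frac_rhythmic * n)
    n_disrupted = round(gcfg.frac_disrupted_given_rhythmic * n_rhythmic)
    n_abolished = round(gcfg.frac_abolished_given_rhythmic * n_rhythmic)
    if n_disrupted + n_abolished > n_rhythmic:
        raise ValueError("disrupted + abolished fractions exceed the rhythmic set")
    n_fc = min(gcfg.n_fc_effects, n - n_rhythmic)

    streams = np.random.SeedSequence(gcfg.seed).spawn(n)
    ids = [f"M{i + 1:04d}" for i in range(n)]
    specs = [_draw_base_spec(np.random.default_rng(streams[i]), i < n_rhythmic, gcfg)
             for i in range(n)]
    # note: parameter draws and noise draws share each metabolite's stream;
    # draws happen in a fixed order so the dataset is reproducible

    # roles ---------------------------------------------------------------
    roles = ["arrhythmic"] * n
    for i in range(n_rhythmic):
        roles[i] = "stable_rhythmic"
    for i in range(n_disrupted):
        roles[i] = "core_disrupted"
    non_core = list(range(n_disrupted, n_rhythmic))
    if gcfg.nocturnal_loss_bias:
        half = gcfg.period / 2
        non_core.sort(key=lambda i: (specs[i].acrophase < half, i))  # night first
    for i in non_core[:n_abolished]:
        roles[i] = "abolished"
    for i in range(n_rhythmic, n_rhythmic + n_fc):
        roles[i] = "fc_effect"

    def effect_for(i: int) -> GroupEffect:
        role = roles[i]
        if role == "core_disrupted":
            return GroupEffect(phase_delay=gcfg.disrupted_phase_delay,
                               amplitude_scale=gcfg.disrupted_amplitude_scale)
        if role == "abolished":
            return GroupEffect(amplitude_scale=0.0)
        if role == "fc_effect":
            return GroupEffect(mesor_shift=(gcfg.fc_effect_size - 1.0) * specs[i].mesor)
        return GroupEffect()

    effects = [effect_for(i) for i in range(n)]

    # samples -------------------------------------------------------------
    t_cell = np.repeat(np.asarray(gcfg.timepoints, float), gcfg.replicates_per_cell)
    sample_ids, meta_rows = [], []
    for group in ("LD", "LL"):
        for zt in gcfg.timepoints:
            for rep in range(1, gcfg.replicates_per_cell + 1):
                sid = f"{group}_ZT{zt:g}_r{rep}"
                sample_ids.append(sid)
                meta_rows.append((sid, group, float(zt), rep))
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "group", "zt", "replicate"])
    meta = meta.set_index("sample_id")

    data = np.empty((n, 2 * t_cell.size))
    total_clipped = 0
    for i in range(n):
        rng = np.random.default_rng(streams[i])
        _ = _draw_base_spec(rng, i < n_rhythmic, gcfg)  # replay parameter draws
        ld, c1 = _sample_series(specs[i], t_cell, rng, gcfg.noise_model)
        ll, c2 = _sample_series(effects[i].apply(specs[i]), t_cell, rng, gcfg.noise_model)
        data[i, :t_cell.size] = ld
        data[i, t_cell.size:] = ll
        total_clipped += c1 + c2
    if total_clipped:
        logger.info("clipped %d negative abundance values at 0", total_clipped)

    abundance = pd.DataFrame(data, index=pd.Index(ids, name="metabolite_id"),
                             columns=sample_ids)
    table = MetaboliteTable(abundance, meta)

    # ground truth --------------------------------------------------------
    rows = []
    for i, (spec, eff) in enumerate(zip(specs, effects)):
        ll_spec = eff.apply(spec)
        if spec.rhythmic and ll_spec.rhythmic:
            d_phase = wrap_phase(eff.phase_delay, gcfg.period)
            d_amp = 100.0 * (eff.amplitude_scale - 1.0)
        elif spec.rhythmic:
            d_phase, d_amp = float("nan"), -100.0
        else:
            d_phase, d_amp = float("nan"), float("nan")
        rows.append(dict(metabolite_id=ids[i], role=roles[i],
                         rhythmic=spec.rhythmic, ll_rhythmic=ll_spec.rhythmic,
                         mesor=spec.mesor, amplitude=spec.amplitude,
                         acrophase=spec.acrophase if spec.rhythmic else float("nan"),
                         sigma=spec.sigma, period=spec.period,
                         phase_delay=eff.phase_delay,
                         amplitude_scale=eff.amplitude_scale,
                         mesor_shift=eff.mesor_shift,
                         true_delta_phase=d_phase,
                         true_amp_change_pct=d_amp))
    gt = GroundTruth(pd.DataFrame(rows).set_index("metabolite_id"), gcfg)
    return table, gt


def true_disruption_summary(gt: GroundTruth) -> pd.DataFrame:
    """True (delta phase, amplitude change %) per LD-rhythmic metabolite,
    with the same wrapping rule as the fitted comparison."""
    sub = gt.table[gt.table["rhythmic"]]
    return sub[["true_delta_phase", "true_amp_change_pct"]].copy()


def synthetic_pathway_map(gt: GroundTruth, n_pathways: int = 10,
                          seed: int = 0):
    """A toy pathway map over the synthetic metabolite IDs.

    The first pathway concentrates the core-disrupted metabolites (so an
    over-representation test on the disrupted hit set has a planted signal);
    the rest are random draws from the panel. Background = full panel.
    """
    from .enrichment import PathwayMap

    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    ids = list(gt.table.index)
    disrupted = gt.disrupted_ids
    pathways: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    fillers = [m for m in ids if m not in disrupted]
    core = disrupted[: max(3, len(disrupted) // 2 + 2)]
    extra = list(rng.choice(fillers, size=6, replace=False))
    pathways["PW001"] = frozenset(core + extra)
    names["PW001"] = "planted disrupted pathway"
    for j in range(2, n_pathways + 1):
        size = int(rng.integers(8, 21))
        members = frozenset(rng.choice(ids, size=size, replace=False))
        pathways[f"PW{j:03d}"] = members
        names[f"PW{j:03d}"] = f"random pathway {j}"
    return PathwayMap(pathways=pathways, names=names, background=frozenset(ids))
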