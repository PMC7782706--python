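"""Synthetic Patch-seq data with planted, recoverable ground truth.

Two generators:

* :func:`simulate_expression` — a TPM matrix over labeled cell types with
  log-normal baseline expression, Bernoulli dropout, planted fold-change
  genes between type pairs, and planted binary on/off transition genes at a
  configurable postnatal age.
* :func:`simulate_sweeps` — voltage- and current-clamp sweeps from a
  single-compartment RC membrane with a logistic F-I law and a piecewise
  linear AP template, so every extracted feature has an analytic truth.

Default cohort sizes follow the study design the package targets: five
morphological PV types (7 vAAC, 9 vBIC, 11 hBIC, 31 vBC, 9 hBC) plus an
SST-OLM control group, ages P10-P77.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CellTable, Dataset, ExpressionMatrix, ValidationError
from .ephys import CurrentClampStep, SweepSet, VoltageClampStep


class ConfigError(ValueError):
    """Raised for an inconsistent simulation configuration."""


@dataclass
class DESpec:
    """Plant a fold change on one gene between two cell types (A over B)."""

    gene_index: int
    type_a: str
    type_b: str
    fold: float

    def __post_init__(self):
        if self.fold <= 0:
            raise ConfigError("fold change must be > 0")


@dataclass
class TransitionSpec:
    """Plant a binary on/off expression switch at a given postnatal age.

    Cells younger than ``onset_age_days`` express the gene with probability
    ``pre_fraction``; cells at or past the onset express it with
    ``post_fraction``.
    """

    gene_index: int
    onset_age_days: int
    pre_fraction: float
    post_fraction: float

    def __post_init__(self):
        for frac in (self.pre_fraction, self.post_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("expression fractions must be in [0, 1]")

    @property
    def direction(self) -> str:
        return "up" if self.post_fraction >= self.pre_fraction else "down"


@dataclass
class EphysSpec:
    """Biophysical ground truth for the RC membrane / spiking simulator.

    Resistances in MOhm, capacitance in pF, F-I logistic
    F(I) = fmax / (1 + exp(-(I - i0)/s)) in Hz and pA.  Noise levels default
    to zero; they are knobs, not claims about recording noise.
    """

    r_in_mohm: float = 120.0
    r_s_mohm: float = 12.0
    c_pf: float = 120.0
    fmax_hz: float = 150.0
    i0_pa: float = 250.0
    s_pa: float = 60.0
    v_rest_mv: float = -65.0
    sag_mv: float = 2.5
    ap_amp_mv: float = 80.0
    ap_rise_ms: float = 0.3
    ap_fall_ms: float = 0.5
    ap_trough_mv: float = 12.0
    attenuation: float = 1.2
    vc_delta_mv: float = 5.0
    cc_current_min_pa: float = -150.0
    cc_current_max_pa: float = 600.0
    cc_current_step_pa: float = 50.0
    cc_duration_ms: float = 1500.0
    sag_duration_ms: float = 2250.0
    sampling_rate_hz: float = 20000.0
    noise_mv: float = 0.0
    noise_pa: float = 0.0

    def __post_init__(self):
        if min(self.r_in_mohm, self.r_s_mohm, self.c_pf) <= 0:
            raise ConfigError("R_in, R_s and C must be positive")


_DEFAULT_COHORT = {
    "vAAC": 7, "vBIC": 9, "hBIC": 11, "vBC": 31, "hBC": 9, "SST-OLM": 9,
}


@dataclass
class SimulationConfig:
    n_cells_per_type: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_COHORT))
    n_genes: int = 1000
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 2.0
    noise_log2_sd: float = 0.7
    dropout_rate: float = 0.3
    de_spec: list[DESpec] = field(default_factory=list)
    transition_spec: list[TransitionSpec] = field(default_factory=list)
    age_range: tuple[int, int] = (10, 77)
    ephys_spec: EphysSpec = field(default_factory=EphysSpec)
    ephys_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.age_range
        if lo > hi or lo < 0:
            raise ConfigError("age_range must satisfy 0 <= min_day <= max_day")
        for spec in list(self.de_spec) + list(self.transition_spec):
            if not 0 <= spec.gene_index < self.n_genes:
                raise ConfigError(f"gene index {spec.gene_index} out of range")
        for spec in self.transition_spec:
            if not lo <= spec.onset_age_days <= hi:
                raise ConfigError("transition onset_age must lie within age_range")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        """Build a config from a plain mapping (e.g. a parsed YAML block)."""
        opts = {k: v for k, v in raw.items() if v is not None}
        if "age_range" in opts:
            opts["age_range"] = tuple(opts["age_range"])
        if "de_spec" in opts:
            opts["de_spec"] = [s if isinstance(s, DESpec) else DESpec(**s)
                               for s in opts["de_spec"]]
        if "transition_spec" in opts:
            opts["transition_spec"] = [
                s if isinstance(s, TransitionSpec) else TransitionSpec(**s)
                for s in opts["transition_spec"]]
        if "ephys_spec" in opts and not isinstance(opts["ephys_spec"], EphysSpec):
            opts["ephys_spec"] = EphysSpec(**opts["ephys_spec"])
        return cls(**opts)


@dataclass
class GroundTruth:
    """Planted truth for a simulated Dataset."""

    de: list[DESpec]
    transitions: list[TransitionSpec]
    gene_names: list[str]
    ephys_by_cell: dict[str, EphysSpec] = field(default_factory=dict)

    def de_genes(self) -> list[str]:
        return [self.gene_names[s.gene_index] for s in self.de]

    def transition_genes(self) -> list[str]:
        return [self.gene_names[s.gene_index] for s in self.transitions]


#: value drawn for an "expressed" transition-gene observation (log2 TPM);
#: comfortably above the 0.6 TPM binarization cutoff.
_TRANSITION_EXPR_LOG2_MEAN = 5.0
_TRANSITION_EXPR_LOG2_SD = 0.5


def simulate_expression(config: SimulationConfig) -> tuple[Dataset, GroundTruth]:
    """Generate an aligned Dataset plus its GroundTruth, deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    types = list(config.n_cells_per_type)
    cell_ids, cell_types = [], []
    for t in types:
        for i in range(config.n_cells_per_type[t]):
            cell_ids.append(f"{t}-{i:03d}")
            cell_types.append(t)
    n_cells = len(cell_ids)
    if n_cells == 0:
        raise ConfigError("no cells requested")
    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n_cells)

    gene_names = [f"G{i:05d}" for i in range(config.n_genes)]
    base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=config.n_genes)
    log2_expr = base[:, None] + rng.normal(0.0, config.noise_log2_sd,
                                           size=(config.n_genes, n_cells))
    tpm = np.exp2(log2_expr)

    type_arr = np.asarray(cell_types)
    for spec in config.de_spec:
        tpm[spec.gene_index, type_arr == spec.type_a] *= spec.fold

    if config.dropout_rate > 0:
        keep = rng.random(size=tpm.shape) >= config.dropout_rate
        tpm = tpm * keep

    # transition genes: binary on/off by age; dropout does not apply, the
    # planted pre/post fractions ARE the expression probabilities
    for spec in config.transition_spec:
        prob = np.where(ages >= spec.onset_age_days, spec.post_fraction, spec.pre_fraction)
        on = rng.random(n_cells) < prob
        vals = np.exp2(rng.normal(_TRANSITION_EXPR_LOG2_MEAN,
                                  _TRANSITION_EXPR_LOG2_SD, size=n_cells))
        tpm[spec.gene_index] = np.where(on, vals, 0.0)

    expr = ExpressionMatrix(pd.DataFrame(tpm, index=gene_names, columns=cell_ids))
    from .data import MORPH_TYPES
    morph = [t if t in MORPH_TYPES else "unclassified" for t in cell_types]
    meta = CellTable(pd.DataFrame({
        "cell_id": cell_ids,
        "age_days": ages,
        "morph_type": morph,
        "sim_type": cell_types,  # generative label, kept verbatim
        "region": "CA1",
    }))
    truth = GroundTruth(
        de=list(config.de_spec),
        transitions=list(config.transition_spec),
        gene_names=gene_names,
    )
    if config.ephys_jitter > 0:
        for cid in cell_ids:
            truth.ephys_by_cell[cid] = _jittered_spec(config, cid)
    return Dataset(expr, meta), truth


def _cell_rng(config: SimulationConfig, cell_id: str) -> np.random.Generator:
    """Stable per-cell RNG: seed combined with a CRC of the cell id."""
    return np.random.default_rng([config.seed, zlib.crc32(cell_id.encode())])


def _jittered_spec(config: SimulationConfig, cell_id: str) -> EphysSpec:
    rng = _cell_rng(config, cell_id)
    j = config.ephys_jitter
    s = config.ephys_spec
    factor = lambda: float(rng.uniform(1 - j, 1 + j))
    return EphysSpec(
        r_in_mohm=s.r_in_mohm * factor(), r_s_mohm=s.r_s_mohm * factor(),
        c_pf=s.c_pf * factor(), fmax_hz=s.fmax_hz * factor(),
        i0_pa=s.i0_pa * factor(), s_pa=s.s_pa * factor(),
        v_rest_mv=s.v_rest_mv, sag_mv=s.sag_mv, ap_amp_mv=s.ap_amp_mv,
        ap_rise_ms=s.ap_rise_ms, ap_fall_ms=s.ap_fall_ms,
        ap_trough_mv=s.ap_trough_mv, attenuation=s.attenuation,
        vc_delta_mv=s.vc_delta_mv,
        cc_current_min_pa=s.cc_current_min_pa, cc_current_max_pa=s.cc_current_max_pa,
        cc_current_step_pa=s.cc_current_step_pa, cc_duration_ms=s.cc_duration_ms,
        sag_duration_ms=s.sag_duration_ms, sampling_rate_hz=s.sampling_rate_hz,
        noise_mv=s.noise_mv, noise_pa=s.noise_pa,
    )


def _render_vc(spec: EphysSpec, rng: np.random.Generator) -> VoltageClampStep:
    dt = 1000.0 / spec.sampling_rate_hz
    onset, step_len, tail = 10.0, 100.0, 10.0
    n = int(round((onset + step_len + tail) / dt))
    t = np.arange(n) * dt
    i_peak = spec.vc_delta_mv / spec.r_s_mohm * 1000.0  # pA
    i_ss = spec.vc_delta_mv / (spec.r_s_mohm + spec.r_in_mohm) * 1000.0
    r_par = spec.r_s_mohm * spec.r_in_mohm / (spec.r_s_mohm + spec.r_in_mohm)
    tau_ms = spec.c_pf * r_par / 1000.0  # pF * MOhm = us
    current = np.zeros(n)
    in_step = (t >= onset) & (t < onset + step_len)
    ts = t[in_step] - onset
    current[in_step] = i_ss + (i_peak - i_ss) * np.exp(-ts / tau_ms)
    post = t >= onset + step_len
    current[post] = -(i_peak - i_ss) * np.exp(-(t[post] - onset - step_len) / tau_ms)
    if spec.noise_pa > 0:
        current = current + rng.normal(0.0, spec.noise_pa, size=n)
    return VoltageClampStep(spec.vc_delta_mv, onset, onset + step_len, t, current)


def _render_cc(spec: EphysSpec, i_inj: float, duration_ms: float,
               rng: np.random.Generator) -> CurrentClampStep:
    dt = 1000.0 / spec.sampling_rate_hz
    onset, tail = 100.0, 100.0
    n = int(round((onset + duration_ms + tail) / dt))
    t = np.arange(n) * dt
    tau_m = spec.r_in_mohm * spec.c_pf / 1000.0  # ms
    dv_ss = i_inj * spec.r_in_mohm / 1000.0  # pA * MOhm / 1000 = mV
    if i_inj > 0:
        dv_ss = min(dv_ss, 20.0)  # cap subthreshold depolarization near spike threshold

    v = np.full(n, spec.v_rest_mv)
    in_step = (t >= onset) & (t < onset + duration_ms)
    ts = t[in_step] - onset
    v[in_step] = spec.v_rest_mv + dv_ss * (1.0 - np.exp(-ts / tau_m))
    post = t >= onset + duration_ms
    v[post] = spec.v_rest_mv + dv_ss * np.exp(-(t[post] - onset - duration_ms) / tau_m)

    if i_inj < 0 and spec.sag_mv > 0 and duration_ms >= 1000.0:
        # sag rendered as a ramp to a trough at 800 ms post-onset, then an
        # exponential relaxation; trough depth equals the configured sag
        t_trough, tau_rec = 800.0, 150.0
        dip = np.zeros(n)
        rel = t[in_step] - onset
        shape = np.where(rel <= t_trough, rel / t_trough,
                         np.exp(-(rel - t_trough) / tau_rec))
        dip[in_step] = spec.sag_mv * shape * np.sign(i_inj)
        v = v + dip

    # spikes per the logistic F-I law, regular inter-spike intervals
    duration_s = duration_ms / 1000.0
    freq = spec.fmax_hz / (1.0 + np.exp(-(i_inj - spec.i0_pa) / spec.s_pa))
    n_sp = int(round(freq * duration_s)) if i_inj > 0 and spec.ap_amp_mv > 0 else 0
    if n_sp > 0:
        isi = duration_ms / n_sp
        rise_n = max(int(round(spec.ap_rise_ms / dt)), 1)
        fall_n = max(int(round(spec.ap_fall_ms / dt)), 1)
        rec_n = max(int(round(1.0 / dt)), 1)
        for k in range(n_sp):
            t_on = onset + (k + 0.5) * isi
            idx = int(round(t_on / dt))
            if n_sp > 1:
                amp = spec.ap_amp_mv * (1.0 - (1.0 - 1.0 / spec.attenuation) * k / (n_sp - 1))
            else:
                amp = spec.ap_amp_mv
            shape = np.concatenate([
                np.linspace(0.0, amp, rise_n + 1)[1:],
                np.linspace(amp, -spec.ap_trough_mv, fall_n + 1)[1:],
                np.linspace(-spec.ap_trough_mv, 0.0, rec_n + 1)[1:],
            ])
            end = min(idx + 1 + len(shape), n)
            # additive on the subthreshold trajectory: no discontinuity at
            # the template end while the membrane is still charging
            v[idx + 1: end] += shape[: end - idx - 1]
    if spec.noise_mv > 0:
        v = v + rng.normal(0.0, spec.noise_mv, size=n)
    return CurrentClampStep(i_inj, onset, onset + duration_ms, t, v)


def simulate_sweeps(config: SimulationConfig, cell_id: str) -> SweepSet:
    """Render the full clamp protocol for one cell, deterministic per (seed, cell)."""
    spec = (_jittered_spec(config, cell_id) if config.ephys_jitter > 0
            else config.ephys_spec)
    rng = _cell_rng(config, cell_id)
    vc = _render_vc(spec, rng)
    currents = np.arange(spec.cc_current_min_pa,
                         spec.cc_current_max_pa + 0.5 * spec.cc_current_step_pa,
                         spec.cc_current_step_pa)
    cc = []
    for i_inj in currents:
        dur = spec.sag_duration_ms if i_inj == -150.0 else spec.cc_duration_ms
        cc.append(_render_cc(spec, float(i_inj), dur, rng))
    return SweepSet(sampling_rate_hz=spec.sampling_rate_hz, vc_step=vc, cc_steps=cc)
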