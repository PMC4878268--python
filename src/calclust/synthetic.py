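"""Labelled synthetic Ca2+ trace datasets with three functional sub-types.

The generator emulates the structure of a dispersed-islet Fura-2 imaging
run: a population of cells recorded simultaneously under the timed
glucose/KCl perfusion protocol, mixing

``oscillating_responder``
    raised high-glucose plateau carrying rhythmic Ca2+ oscillations
    (sinusoid with per-cell random phase and period jitter);
``non_oscillating_responder``
    rapid sigmoid rise to a raised plateau with little high-glucose
    oscillation, but residual slow oscillation during the second
    low-glucose window instead of a complete return to baseline;
``non_responder``
    flat through both glucose windows (alpha-cell-like), with small
    spontaneous low-glucose fluctuations, responding only to KCl;
``kcl_dead``
    no response even to KCl depolarization (non-excitable or unhealthy
    cells) — the population the QC filter should remove.

All response amplitudes are parameterised as fractions of the per-cell KCl
step, so the affine-invariant feature definitions see the same geometry
regardless of per-cell dye loading.  Every cell gets a mild linear drift
and additive Gaussian measurement noise.  Cells are spread over imaging
fields with non-responders enriched in the last field, emulating
inhomogeneous dispersion of the tissue.

Generation is fully deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Protocol, TraceDataset, default_protocol

OSCILLATOR = "oscillating_responder"
NON_OSCILLATOR = "non_oscillating_responder"
NON_RESPONDER = "non_responder"
KCL_DEAD = "kcl_dead"
CELL_TYPES = (OSCILLATOR, NON_OSCILLATOR, NON_RESPONDER, KCL_DEAD)


@dataclass(frozen=True)
class CellTypeKinetics:
    """Per-type trace kinetics; amplitudes are fractions of the KCl step.

    ``response_fraction``: plateau height during high glucose.
    ``oscillation_fraction``: sinusoid amplitude during high glucose.
    ``period_min``: oscillation period (minutes), jittered per cell.
    ``latency_min``: delay from high-glucose onset to the response.
    ``post_low_oscillation_fraction``: residual oscillation amplitude during
    the second low-glucose window (non-oscillating responders).
    ``overshoot_fraction``: first-phase (phase-1) overshoot above the
    plateau at glucose onset, decaying with ``overshoot_tau_min``.
    ``pre_low_oscillation_fraction``: spontaneous fluctuation amplitude
    during the first low-glucose window (non-responders).
    """

    response_fraction: float = 0.0
    response_fraction_sd: float = 0.0
    oscillation_fraction: float = 0.0
    oscillation_fraction_sd: float = 0.0
    period_min: float = 3.5
    period_jitter: float = 0.10
    latency_min: float = 1.0
    latency_sd: float = 0.3
    post_low_oscillation_fraction: float = 0.0
    post_low_oscillation_sd: float = 0.0
    overshoot_fraction: float = 0.0
    overshoot_sd: float = 0.0
    overshoot_tau_min: float = 1.5
    pre_low_oscillation_fraction: float = 0.0
    pre_low_oscillation_sd: float = 0.0
    kcl_responsive: bool = True


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a synthetic imaging run.

    ``weights`` order follows :data:`CELL_TYPES`: (oscillating responder,
    non-oscillating responder, non-responder, kcl_dead); they must be
    non-negative and sum to 1.  ``noise_sd`` is the additive Gaussian
    measurement noise in ratio units (the mean KCl step is 1.0 ratio unit,
    so 0.02 is 2% of the depolarization amplitude).  ``drift_slope_mean`` /
    ``sd`` set the per-cell linear drift in ratio units per minute.
    """

    n_cells: int = 300
    weights: tuple[float, float, float, float] = (0.40, 0.31, 0.24, 0.05)
    n_fields: int = 3
    responder_field_probs: tuple[float, ...] | None = None
    non_responder_field_probs: tuple[float, ...] | None = None
    n_timepoints: int = 480
    total_min: float = 80.0
    baseline_level: float = 1.0
    baseline_level_sd: float = 0.05
    kcl_amplitude: float = 1.0
    kcl_amplitude_sd: float = 0.10
    drift_slope_mean: float = 0.002
    drift_slope_sd: float = 0.001
    noise_sd: float = 0.02
    kinetics: dict[str, CellTypeKinetics] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        w = np.asarray(self.weights, float)
        if len(w) != 4 or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be 4 non-negative values summing to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_fields < 1:
            raise ValueError("n_fields must be >= 1")
        if not self.kinetics:
            object.__setattr__(self, "kinetics", default_kinetics())
        for probs in (self.responder_field_probs, self.non_responder_field_probs):
            if probs is not None and (
                len(probs) != self.n_fields or not np.isclose(sum(probs), 1.0)
            ):
                raise ValueError(f"field probabilities must have {self.n_fields} entries summing to 1")


def default_kinetics() -> dict[str, CellTypeKinetics]:
    """Kinetics of the four cell types in the canonical preset.

    Oscillating responders plateau at ~50% of the KCl step and oscillate
    with ~25% amplitude at a ~3.5 min period (the few-minute glucose-driven
    Ca2+ oscillations typical of healthy beta cells).  Non-oscillating
    responders rise faster (rapid responders) to a slightly higher plateau
    and instead show slow residual oscillation during the second low-glucose
    window.  Non-responders carry only small spontaneous low-glucose
    fluctuations.  kcl_dead cells are flat everywhere.
    """
    return {
        OSCILLATOR: CellTypeKinetics(
            response_fraction=0.50,
            response_fraction_sd=0.10,
            oscillation_fraction=0.25,
            oscillation_fraction_sd=0.05,
            period_min=3.5,
            period_jitter=0.10,
            latency_min=1.2,
            latency_sd=0.4,
        ),
        NON_OSCILLATOR: CellTypeKinetics(
            response_fraction=0.60,
            response_fraction_sd=0.10,
            latency_min=0.4,
            latency_sd=0.15,
            period_min=4.0,
            post_low_oscillation_fraction=0.12,
            post_low_oscillation_sd=0.04,
            overshoot_fraction=0.60,
            overshoot_sd=0.15,
            overshoot_tau_min=2.0,
        ),
        NON_RESPONDER: CellTypeKinetics(
            latency_min=0.0,
            latency_sd=0.0,
            period_min=2.0,
            pre_low_oscillation_fraction=0.05,
            pre_low_oscillation_sd=0.02,
        ),
        KCL_DEAD: CellTypeKinetics(latency_min=0.0, latency_sd=0.0, kcl_responsive=False),
    }


def paperlike_preset(seed: int = 0) -> SyntheticConfig:
    """The repository's canonical fixture configuration.

    300 cells over 3 imaging fields, 480 timepoints over 80 min (10 s
    sampling), sub-type weights (0.40, 0.31, 0.24, 0.05) for oscillating
    responders, non-oscillating responders, non-responders and kcl_dead
    cells respectively, with non-responders enriched in the third field.
    Noise (2% of the mean KCl step) and drift (~0.2% per minute) are small
    relative to the depolarization amplitude.
    """
    return SyntheticConfig(
        n_cells=300,
        weights=(0.40, 0.31, 0.24, 0.05),
        n_fields=3,
        responder_field_probs=(0.40, 0.40, 0.20),
        non_responder_field_probs=(0.20, 0.20, 0.60),
        seed=seed,
    )


def _logistic(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - center) / width))


def _simulate_cell(
    t: np.ndarray,
    cell_type: str,
    kin: CellTypeKinetics,
    cfg: SyntheticConfig,
    protocol: Protocol,
    rng: np.random.Generator,
) -> np.ndarray:
    hg = protocol.find("high_glucose", 1)
    low2 = protocol.find("low_glucose", 2)
    kcl = protocol.find("kcl", 1)
    b = max(0.2, rng.normal(cfg.baseline_level, cfg.baseline_level_sd))
    amp = max(0.3, rng.normal(cfg.kcl_amplitude, cfg.kcl_amplitude_sd))
    slope = rng.normal(cfg.drift_slope_mean, cfg.drift_slope_sd)
    # draws below are unconditional so the rng stream is identical across types
    r = max(0.0, rng.normal(kin.response_fraction, kin.response_fraction_sd))
    a = max(0.0, rng.normal(kin.oscillation_fraction, kin.oscillation_fraction_sd))
    period = kin.period_min * (1.0 + rng.uniform(-kin.period_jitter, kin.period_jitter))
    latency = max(0.0, rng.normal(kin.latency_min, kin.latency_sd))
    phase = rng.uniform(0.0, 2.0 * np.pi)
    overshoot = max(0.0, rng.normal(kin.overshoot_fraction, kin.overshoot_sd))
    post_amp = max(0.0, rng.normal(kin.post_low_oscillation_fraction, kin.post_low_oscillation_sd))
    post_phase = rng.uniform(0.0, 2.0 * np.pi)
    pre_amp = max(0.0, rng.normal(kin.pre_low_oscillation_fraction, kin.pre_low_oscillation_sd))
    pre_phase = rng.uniform(0.0, 2.0 * np.pi)

    x = np.full_like(t, b)
    t_on = hg.start + latency
    rise = _logistic(t, t_on, 0.2)
    # plateau holds through high glucose, then decays during the second low window
    decay = np.where(t >= hg.end, np.exp(-(t - hg.end) / 1.5), 1.0)
    plateau_env = np.where(t < hg.start, 0.0, rise * decay)
    x = x + r * amp * plateau_env
    if overshoot > 0:
        # first-phase transient: sharp rise with the plateau, then decay
        x = x + overshoot * amp * plateau_env * np.exp(
            -np.clip(t - t_on, 0.0, None) / kin.overshoot_tau_min
        )
    if a > 0:
        osc_env = np.where(t >= hg.end, np.exp(-(t - hg.end) / 0.5), rise)
        osc_env = np.where(t < hg.start, 0.0, osc_env)
        x = x + a * amp * np.sin(2.0 * np.pi * (t - t_on) / period + phase) * osc_env
    if post_amp > 0:
        in_low2 = (t >= low2.start) & (t < low2.end)
        x = x + post_amp * amp * np.sin(
            2.0 * np.pi * (t - low2.start) / kin.period_min + post_phase
        ) * in_low2
    if pre_amp > 0:
        in_pre = t < hg.start
        x = x + pre_amp * amp * np.sin(2.0 * np.pi * t / kin.period_min + pre_phase) * in_pre
    if kin.kcl_responsive:
        kcl_env = np.where(
            t < kcl.end, _logistic(t, kcl.start, 0.1), np.exp(-(t - kcl.end) / 1.0)
        )
        kcl_env = np.where(t < kcl.start - 1.0, 0.0, kcl_env)
        x = x + amp * kcl_env
    x = x + slope * (t - t[0])
    if cfg.noise_sd > 0:
        x = x + rng.normal(0.0, cfg.noise_sd, size=t.shape)
    return x


def generate_dataset(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[TraceDataset, list[str]]:
    """Simulate a run; returns the dataset and per-cell ground-truth labels.

    ``seed`` overrides ``config.seed`` when given.  Output is bit-identical
    for a fixed seed.  Cell types are drawn from ``config.weights``; imaging
    fields from the type-specific field probabilities (uniform when unset).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    protocol = default_protocol()
    if config.total_min != 80.0:
        raise ValueError("only the 80-minute default protocol is generated")
    t = np.arange(config.n_timepoints) * (config.total_min / config.n_timepoints)
    labels = [CELL_TYPES[i] for i in rng.choice(4, size=config.n_cells, p=list(config.weights))]
    uniform = tuple(1.0 / config.n_fields for _ in range(config.n_fields))
    resp_probs = config.responder_field_probs or uniform
    nonresp_probs = config.non_responder_field_probs or uniform
    field_names = [f"field_{i + 1}" for i in range(config.n_fields)]
    fields = [
        field_names[
            rng.choice(
                config.n_fields,
                p=list(nonresp_probs if lab in (NON_RESPONDER, KCL_DEAD) else resp_probs),
            )
        ]
        for lab in labels
    ]
    values = np.empty((config.n_cells, config.n_timepoints))
    for i, lab in enumerate(labels):
        values[i] = _simulate_cell(t, lab, config.kinetics[lab], config, protocol, rng)
    positions = rng.uniform(0.0, 512.0, size=(config.n_cells, 2))
    width = len(str(config.n_cells))
    dataset = TraceDataset(
        cell_ids=[f"cell_{i + 1:0{width}d}" for i in range(config.n_cells)],
        field_ids=fields,
        times=t,
        values=values,
        positions=positions,
    )
    return dataset, labels


__all__ = [
    "OSCILLATOR",
    "NON_OSCILLATOR",
    "NON_RESPONDER",
    "KCL_DEAD",
    "CELL_TYPES",
    "CellTypeKinetics",
    "SyntheticConfig",
    "default_kinetics",
    "paperlike_preset",
    "generate_dataset",
]
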