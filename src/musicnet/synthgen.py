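"""Synthetic cohorts and audio with planted, exported ground truth.

The study design this emulates: two groups of musicians (24 aspiring
professionals, 17 amateurs) listen to two 5-minute pieces while 112-parcel
ROI time series are recorded at TR = 2 s (140 volumes per condition).  Since
no such recordings ship with the package, the generator plants the structure
the analysis is meant to recover:

- two latent connectivity regimes — a *modular* one (block-structured
  correlations) and an *integrated* one (uniform off-diagonal correlation
  with higher global efficiency) — alternating within a run as a first-order
  Markov chain;
- condition-dependent dwell: condition 1 is biased toward the modular
  regime, condition 2 toward the integrated regime;
- a group effect: group A's between-block correlations in condition 2 are
  boosted by ``group_effect_delta`` so their planted static global
  efficiency is higher;
- optional per-60-s-segment coupling between audio complexity (the noise
  mixing weight alpha) and the modular-regime probability, so segment-wise
  audio entropy anticorrelates with modular-state occupancy.

Audio is ``s(t) = (1-alpha) * harmonic + alpha * white noise`` with alpha
constant per segment; its per-segment permutation entropy increases with
alpha.  All randomness flows from a single seed; sub-seeds are derived
deterministically per subject, so identical specs give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import RoiTimeSeries
from .audiofeat import AudioSignal, write_wav
from . import graphmetrics

__all__ = [
    "StateCovariance",
    "CohortSpec",
    "GroundTruth",
    "make_state_covariances",
    "markov_schedule",
    "simulate_subject",
    "simulate_cohort",
    "synth_audio",
    "small_profile",
    "study_profile",
    "write_cohort",
]

MODULAR = 0
INTEGRATED = 1
REGIME_NAMES = {MODULAR: "modular", INTEGRATED: "integrated"}


@dataclass
class StateCovariance:
    """Unit-diagonal PSD correlation matrix defining one latent regime."""

    matrix: np.ndarray
    regime: str  # "modular" | "integrated"
    block_assignment: np.ndarray | None = None

    def __post_init__(self) -> None:
        C = np.asarray(self.matrix, dtype=float)
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        eigmin = np.linalg.eigvalsh(C).min()
        if eigmin < -1e-10:
            raise ValueError(f"covariance not PSD (min eigenvalue {eigmin:.2e})")
        if not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise ValueError("diagonal must be exactly 1")
        self.matrix = C


@dataclass
class CohortSpec:
    """Design of a synthetic cohort.  Defaults mirror the study conditions."""

    n_group_a: int = 24  # "aspiring professionals"
    n_group_b: int = 17  # "amateurs"
    n_parcels: int = 112
    n_timepoints_per_condition: int = 140
    tr_seconds: float = 2.0
    n_blocks: int = 4
    r_within: float = 0.7
    r_between_modular: float = 0.1
    r_uniform_integrated: float = 0.4
    # per-condition stationary probability of the modular regime
    dwell_bias: dict = field(default_factory=lambda: {"cond1": 0.62, "cond2": 0.38})
    mean_dwell_s: float = 30.0
    group_effect_delta: float = 0.075
    # optional per-60-s-segment modular probability (overrides dwell_bias)
    segment_modular_prob: dict | None = None
    segment_length_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_group_a, self.n_group_b, self.n_parcels) <= 0:
            raise ValueError("counts must be positive")
        for v in self.dwell_bias.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("dwell probabilities must lie in [0, 1]")
        window_samples = int(round(60.0 / self.tr_seconds))
        if self.n_timepoints_per_condition < window_samples:
            raise ValueError("n_timepoints must cover at least one 60-s window")

    @property
    def conditions(self) -> list[str]:
        return list(self.dwell_bias.keys())


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests."""

    schedules: dict  # (subject_id, condition) -> regime label per time point
    covariances: dict  # regime name -> StateCovariance (baseline pair)
    group_effect_delta: float
    groups: dict  # subject_id -> "A" | "B"

    def modular_fraction(self, condition: str) -> float:
        vals = [
            (sched == MODULAR).mean()
            for (subj, cond), sched in self.schedules.items()
            if cond == condition
        ]
        return float(np.mean(vals))


def small_profile(**overrides) -> CohortSpec:
    """Fast test profile: 12 subjects (7 + 5), 20 parcels."""
    base = dict(n_group_a=7, n_group_b=5, n_parcels=20, n_blocks=4)
    base.update(overrides)
    return CohortSpec(**base)


def study_profile(**overrides) -> CohortSpec:
    """Study-sized profile: 24 + 17 subjects, 112 parcels."""
    return CohortSpec(**overrides)


# Per-60-s-segment audio noise weights: condition 1 is the clearly tonal,
# low-complexity piece, condition 2 the noisy, high-complexity one.
DEFAULT_SEGMENT_ALPHAS = {
    "cond1": (0.0, 0.1, 0.2, 0.3, 0.4),
    "cond2": (0.5, 0.625, 0.75, 0.875, 1.0),
}
# Modular-regime probability per segment: p = base - slope * alpha, so audio
# complexity and segregated-state occupancy are anticorrelated by design.
COUPLING_BASE = 0.9
COUPLING_SLOPE = 0.7


def entropy_coupled_profile(
    seed: int = 0,
    small: bool = True,
    segment_alphas: dict | None = None,
    base: float = COUPLING_BASE,
    slope: float = COUPLING_SLOPE,
    **overrides,
) -> tuple[CohortSpec, dict]:
    """Cohort spec whose regime schedule is coupled to audio complexity.

    Returns the spec and the per-condition segment alphas to synthesize the
    matching audio with.  Each 60-s segment's modular-regime probability is
    ``base - slope * alpha`` for that segment's audio noise weight alpha.
    """
    alphas = segment_alphas or DEFAULT_SEGMENT_ALPHAS
    probs = {
        cond: [float(np.clip(base - slope * a, 0.0, 1.0)) for a in al]
        for cond, al in alphas.items()
    }
    make = small_profile if small else study_profile
    spec = make(seed=seed, segment_modular_prob=probs, **overrides)
    return spec, alphas


# ---------------------------------------------------------------------------
# Covariance construction


def _psd_repair(C: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues to 0, then rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh((C + C.T) / 2.0)
    C = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    d = np.sqrt(np.diag(C))
    if (d <= 0).any():
        raise ValueError("PSD repair produced a zero-variance dimension")
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return (C + C.T) / 2.0


def _block_assignment(n_parcels: int, n_blocks: int) -> np.ndarray:
    """Near-equal contiguous blocks (sizes differ by at most one)."""
    sizes = np.full(n_blocks, n_parcels // n_blocks)
    sizes[: n_parcels % n_blocks] += 1
    return np.repeat(np.arange(n_blocks), sizes)


def make_state_covariances(
    n_parcels: int = 112,
    n_blocks: int = 4,
    r_within: float = 0.7,
    r_between_modular: float = 0.1,
    r_uniform_integrated: float = 0.4,
    check_separation: bool = True,
) -> tuple[StateCovariance, StateCovariance]:
    """Build the modular and integrated regime correlation matrices.

    The modular matrix has within-block correlation ``r_within`` and
    between-block correlation ``r_between_modular``; the integrated matrix
    has uniform off-diagonal ``r_uniform_integrated``.  Both are projected to
    the nearest PSD matrix with unit diagonal restored.  With
    ``check_separation`` the planted contrast is asserted at construction:
    Louvain Q differs by >= 0.1 and global efficiency by >= 0.05, with Q
    higher for the modular matrix and efficiency higher for the integrated.
    """
    if not (0.0 <= r_between_modular < r_within <= 1.0) and check_separation:
        raise ValueError("need 0 <= r_between_modular < r_within <= 1")
    if not (0.0 <= r_between_modular <= 1.0 and r_within <= 1.0):
        raise ValueError("correlations must lie in [0, 1]")
    if not 0.0 <= r_uniform_integrated <= 1.0:
        raise ValueError("r_uniform_integrated must lie in [0, 1]")

    blocks = _block_assignment(n_parcels, n_blocks)
    same = blocks[:, None] == blocks[None, :]
    C_mod = np.where(same, r_within, r_between_modular)
    np.fill_diagonal(C_mod, 1.0)
    C_int = np.full((n_parcels, n_parcels), r_uniform_integrated)
    np.fill_diagonal(C_int, 1.0)
    C_mod = _psd_repair(C_mod)
    C_int = _psd_repair(C_int)
    modular = StateCovariance(C_mod, "modular", blocks)
    integrated = StateCovariance(C_int, "integrated")

    if check_separation:
        q_m, e_m = _offdiag_metrics(C_mod)
        q_i, e_i = _offdiag_metrics(C_int)
        if not (q_m - q_i >= 0.1 and e_i - e_m >= 0.05):
            raise ValueError(
                "planted regimes not separated: "
                f"Q {q_m:.3f} vs {q_i:.3f}, E {e_m:.3f} vs {e_i:.3f}"
            )
    return modular, integrated


def _offdiag_metrics(C: np.ndarray) -> tuple[float, float]:
    W = np.maximum(C.copy(), 0.0)
    np.fill_diagonal(W, 0.0)
    part = graphmetrics.louvain_partition(W, n_runs=20, seed=0)
    e_glob, _ = graphmetrics.global_efficiency(W)
    return part.quality_q, e_glob


# ---------------------------------------------------------------------------
# Regime schedules and subject simulation


def markov_schedule(
    n_timepoints: int,
    p_modular: float,
    mean_dwell_samples: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """First-order Markov chain over {modular, integrated}.

    Transition rates are scaled so the stationary distribution is
    ``(p_modular, 1 - p_modular)`` and the switching timescale is
    ``mean_dwell_samples``.  The initial state is drawn from the stationary
    distribution.
    """
    tau = max(mean_dwell_samples, 1.0)
    p = float(np.clip(p_modular, 0.0, 1.0))
    leave_mod = min((1.0 - p) / tau, 1.0)
    leave_int = min(p / tau, 1.0)
    out = np.empty(n_timepoints, dtype=int)
    state = MODULAR if rng.random() < p else INTEGRATED
    for t in range(n_timepoints):
        out[t] = state
        u = rng.random()
        if state == MODULAR and u < leave_mod:
            state = INTEGRATED
        elif state == INTEGRATED and u < leave_int:
            state = MODULAR
    return out


def _segment_schedule(
    n_timepoints: int,
    segment_probs: np.ndarray,
    segment_samples: int,
    mean_dwell_samples: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Markov schedule with per-segment stationary modular probability."""
    parts = []
    t = 0
    i = 0
    while t < n_timepoints:
        n = min(segment_samples, n_timepoints - t)
        p = segment_probs[min(i, len(segment_probs) - 1)]
        parts.append(markov_schedule(n, p, mean_dwell_samples, rng))
        t += n
        i += 1
    return np.concatenate(parts)


def _factor(C: np.ndarray) -> np.ndarray:
    """Symmetric square root usable for possibly singular covariances."""
    vals, vecs = np.linalg.eigh(C)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def simulate_subject(
    covariances: dict[int, np.ndarray],
    regime_schedule: np.ndarray,
    tr_seconds: float = 2.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    subject_id: str | None = None,
    condition: str | None = None,
) -> RoiTimeSeries:
    """Zero-mean multivariate normal draws following a regime schedule.

    Each time point is drawn with the covariance of its scheduled regime.
    The standard-normal innovations are drawn once up front, so the output is
    bit-identical for identical (inputs, seed) regardless of the schedule's
    regime composition.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    schedule = np.asarray(regime_schedule, dtype=int)
    n_parcels = next(iter(covariances.values())).shape[0]
    for C in covariances.values():
        if C.shape != (n_parcels, n_parcels):
            raise ValueError("covariance dimensions disagree")
    T = len(schedule)
    Z = rng.standard_normal((T, n_parcels))
    X = np.empty_like(Z)
    for regime, C in covariances.items():
        mask = schedule == regime
        if mask.any():
            X[mask] = Z[mask] @ _factor(C).T
    return RoiTimeSeries(X, tr_seconds, subject_id=subject_id, condition=condition)


def simulate_cohort(spec: CohortSpec) -> tuple[list[RoiTimeSeries], GroundTruth]:
    """Generate every subject x condition run plus the planted ground truth.

    Group A in the second condition has ``group_effect_delta`` added to all
    between-block correlations of both regimes, raising its planted static
    global efficiency.
    """
    modular, integrated = make_state_covariances(
        spec.n_parcels,
        spec.n_blocks,
        spec.r_within,
        spec.r_between_modular,
        spec.r_uniform_integrated,
    )
    blocks = modular.block_assignment
    same = blocks[:, None] == blocks[None, :]

    def boosted(C: np.ndarray, delta: float) -> np.ndarray:
        B = C + np.where(same, 0.0, delta)
        np.fill_diagonal(B, 1.0)
        return _psd_repair(B)

    cov_base = {MODULAR: modular.matrix, INTEGRATED: integrated.matrix}
    cov_boost = {
        MODULAR: boosted(modular.matrix, spec.group_effect_delta),
        INTEGRATED: boosted(integrated.matrix, spec.group_effect_delta),
    }

    ss = np.random.SeedSequence(spec.seed)
    n_subjects = spec.n_group_a + spec.n_group_b
    child_seeds = ss.spawn(n_subjects)
    dwell_samples = spec.mean_dwell_s / spec.tr_seconds
    segment_samples = int(round(spec.segment_length_s / spec.tr_seconds))

    runs: list[RoiTimeSeries] = []
    schedules: dict = {}
    groups: dict = {}
    conditions = spec.conditions
    for s in range(n_subjects):
        subject_id = f"sub-{s:03d}"
        group = "A" if s < spec.n_group_a else "B"
        groups[subject_id] = group
        rng = np.random.default_rng(child_seeds[s])
        for ci, cond in enumerate(conditions):
            if spec.segment_modular_prob is not None:
                sched = _segment_schedule(
                    spec.n_timepoints_per_condition,
                    np.asarray(spec.segment_modular_prob[cond], dtype=float),
                    segment_samples,
                    dwell_samples,
                    rng,
                )
            else:
                sched = markov_schedule(
                    spec.n_timepoints_per_condition,
                    spec.dwell_bias[cond],
                    dwell_samples,
                    rng,
                )
            use_boost = group == "A" and ci == 1 and spec.group_effect_delta != 0
            covs = cov_boost if use_boost else cov_base
            runs.append(
                simulate_subject(
                    covs, sched, spec.tr_seconds, rng=rng,
                    subject_id=subject_id, condition=cond,
                )
            )
            schedules[(subject_id, cond)] = sched
    truth = GroundTruth(
        schedules=schedules,
        covariances={"modular": modular, "integrated": integrated},
        group_effect_delta=spec.group_effect_delta,
        groups=groups,
    )
    return runs, truth


# ---------------------------------------------------------------------------
# Audio synthesis

# C-major triad partials (C4, E4, G4, C5): a clearly tonal harmonic bed
HARMONIC_FREQS = (261.63, 329.63, 392.00, 523.25)


def synth_audio(
    duration_s: float,
    sample_rate: float = 4000.0,
    segment_alphas=(0.0, 0.25, 0.5, 0.75, 1.0),
    segment_length_s: float = 60.0,
    seed: int = 0,
    harmonic_freqs: tuple[float, ...] = HARMONIC_FREQS,
) -> AudioSignal:
    """Harmonic/noise mixture whose ordinal complexity is set per segment.

    ``s(t) = (1-alpha) * harmonic + alpha * noise`` with the harmonic
    component (a fixed C-major chord) normalized to unit RMS and the noise
    iid standard normal; alpha is constant within each 60-s segment, so
    per-segment permutation entropy increases with alpha.
    """
    alphas = np.asarray(segment_alphas, dtype=float)
    if ((alphas < 0) | (alphas > 1)).any():
        raise ValueError("alphas must lie in [0, 1]")
    n_seg = int(round(duration_s / segment_length_s))
    if abs(n_seg * segment_length_s - duration_s) > 1e-9 or n_seg < 1:
        raise ValueError("duration must be a positive multiple of the segment length")
    if len(alphas) != n_seg:
        raise ValueError("need one alpha per segment")
    if sample_rate < 2 * max(harmonic_freqs):
        raise ValueError("sample rate below Nyquist for the harmonic content")

    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    harmonic = sum(np.sin(2 * np.pi * f * t) for f in harmonic_freqs)
    harmonic = harmonic / np.sqrt(np.mean(harmonic**2))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n)
    seg_len = int(round(segment_length_s * sample_rate))
    alpha_t = np.repeat(alphas, seg_len)[:n]
    return AudioSignal((1.0 - alpha_t) * harmonic + alpha_t * noise, sample_rate)


# ---------------------------------------------------------------------------
# Writers


def write_cohort(
    out_dir, runs: list[RoiTimeSeries], truth: GroundTruth, spec: CohortSpec
) -> pd.DataFrame:
    """Write per-run TSVs, ground truth JSON, and the cohort design CSV."""
    out = Path(out_dir)
    ts_dir = out / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for run in runs:
        fname = f"{run.subject_id}_{run.condition}.tsv"
        pd.DataFrame(run.values, columns=run.parcel_names).to_csv(
            ts_dir / fname, sep="\t", index=False
        )
        rows.append(
            {
                "subject_id": run.subject_id,
                "group": truth.groups[run.subject_id],
                "condition": run.condition,
                "path": str(Path("timeseries") / fname),
            }
        )
    design = pd.DataFrame(rows)
    design.to_csv(out / "design.csv", index=False)
    gt = {
        "group_effect_delta": truth.group_effect_delta,
        "groups": truth.groups,
        "schedules": {
            f"{subj}|{cond}": sched.tolist()
            for (subj, cond), sched in truth.schedules.items()
        },
        "regime_names": {str(k): v for k, v in REGIME_NAMES.items()},
        "spec": {
            k: (v if not isinstance(v, dict) else v)
            for k, v in vars(spec).items()
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(gt, sort_keys=True))
    return design
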