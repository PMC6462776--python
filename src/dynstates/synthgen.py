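"""Synthetic resting-state cohort generator.

Emulates the statistical structure a sliding-window connectivity-state
analysis assumes: each subject's network time courses are zero-mean
multivariate Gaussian emissions whose covariance switches among a small
set of latent "connectivity states" according to a first-order Markov
chain.  Group membership changes only the Markov dynamics (occupancy and
dwell), never the emission covariances, so any group difference the
downstream statistics detect is by construction a *dynamics* effect.

On top of the stateful signal the generator can inject polynomial
trends, sparse additive spikes and white noise, which exercise the
postprocessing chain (detrend / despike / low-pass).

Ground truth (latent state sequence per subject, injected spike
positions) is returned alongside the data for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .postproc import TimecourseSet

__all__ = [
    "StateModel",
    "MarkovSpec",
    "GroupSpec",
    "CohortSpec",
    "GroundTruth",
    "generate_state_model",
    "simulate_subject",
    "simulate_cohort",
    "stationary_distribution",
    "window_state_labels",
    "default_cohort_spec",
    "well_separated_scenario",
    "default_network_names",
    "write_cohort",
]

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StateModel:
    """A set of latent connectivity states, each an SPD correlation matrix."""

    covariances: tuple[np.ndarray, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        for lab, cov in zip(self.labels, self.covariances):
            cov = np.asarray(cov, dtype=float)
            if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
                raise ValueError(f"state {lab!r}: covariance must be square")
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"state {lab!r}: covariance not symmetric")
            if not np.allclose(np.diag(cov), 1.0, atol=1e-10):
                raise ValueError(f"state {lab!r}: diagonal must be 1 (correlation scale)")
            if np.linalg.eigvalsh(cov)[0] <= 0:
                raise ValueError(f"state {lab!r}: covariance not positive definite")

    @property
    def n_states(self) -> int:
        return len(self.covariances)

    @property
    def n_networks(self) -> int:
        return self.covariances[0].shape[0]


@dataclass(frozen=True)
class MarkovSpec:
    """Initial distribution and row-stochastic transition matrix."""

    initial_probs: np.ndarray
    transition_matrix: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.initial_probs, dtype=float)
        P = np.asarray(self.transition_matrix, dtype=float)
        object.__setattr__(self, "initial_probs", pi)
        object.__setattr__(self, "transition_matrix", P)
        if pi.ndim != 1 or P.shape != (pi.size, pi.size):
            raise ValueError("transition matrix must be square, matching initial_probs")
        if np.any(pi < 0) or np.any(P < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("initial probabilities must sum to 1")
        if np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("transition matrix rows must sum to 1")

    @property
    def n_states(self) -> int:
        return self.initial_probs.size


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n_subjects: int
    markov: MarkovSpec

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")


@dataclass
class CohortSpec:
    """Everything needed to simulate a cohort deterministically."""

    groups: list[GroupSpec]
    state_model: StateModel
    T: int = 128
    tr: float = 3.0
    noise_sd: float = 0.3
    trend_scale: float = 0.5
    spike_rate: float = 0.002
    spike_amplitude: float = 6.0
    # per-group covariate distributions: (age_mean, age_sd, frac_female, frac_study2)
    covariates: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)
    clinical: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        for g in self.groups:
            if g.markov.n_states != self.state_model.n_states:
                raise ValueError(
                    f"group {g.name!r}: Markov spec has {g.markov.n_states} states, "
                    f"state model has {self.state_model.n_states}"
                )


@dataclass
class GroundTruth:
    """Latent truth for one simulated subject (states are 1-based)."""

    states: np.ndarray          # length T, values in 1..n_states
    group: str
    spike_positions: list[tuple[int, int]]  # (time, network) cells that got a spike


# ---------------------------------------------------------------------------
# State-model construction
# ---------------------------------------------------------------------------


def _default_modules(n_networks: int) -> list[int]:
    """Partition networks into 5 near-equal functional modules."""
    n_mod = min(5, n_networks)
    base = n_networks // n_mod
    sizes = [base] * n_mod
    for i in range(n_networks - base * n_mod):
        sizes[i] += 1
    return sizes


def default_network_names(n_networks: int = 27) -> list[str]:
    """Module-prefixed network names (motor, visual, default-mode, attention,
    cognitive-control), mirroring the functional grouping of typical RSN sets."""
    prefixes = ["MOT", "VIS", "DMN", "ATT", "CCN"]
    sizes = _default_modules(n_networks)
    names = []
    for p, s in zip(prefixes, sizes):
        names.extend(f"{p}{i + 1}" for i in range(s))
    # n_networks < 5 -> fewer modules than prefixes
    return names[:n_networks]


def _shrink_to_spd(R: np.ndarray, min_eig: float, label: str) -> np.ndarray:
    """Shrink a unit-diagonal symmetric matrix toward identity until its
    smallest eigenvalue is >= min_eig."""
    lam = np.linalg.eigvalsh(R)[0]
    if lam < min_eig:
        # eigenvalues of a*R + (1-a)*I are a*lam + (1-a)
        a = (1.0 - min_eig) / (1.0 - lam)
        if not (0.0 < a <= 1.0):
            raise ValueError(f"state {label!r}: cannot shrink to positive definite")
        R = a * R + (1.0 - a) * np.eye(R.shape[0])
    np.fill_diagonal(R, 1.0)
    if np.linalg.eigvalsh(R)[0] <= 0:
        raise ValueError(f"state {label!r}: construction not positive definite")
    return R


def generate_state_model(
    n_states: int = 3,
    n_networks: int = 27,
    block_structure: list[int] | None = None,
    strength: float = 0.6,
    min_eig: float = 0.05,
    scales: tuple[float, ...] | None = None,
) -> StateModel:
    """Build ``n_states`` signed block-structured correlation matrices.

    Each state is a two-factor model Sigma = L L' + psi I normalized to unit
    diagonal, with factor loadings assigned blockwise over the functional
    modules: state s loads modules (2s, 2s+1) mod M positively, module
    (2s+2) mod M negatively (anticorrelation), and module (2s+3) mod M on a
    second, independent factor, so successive states have genuinely distinct
    correlation patterns rather than scaled copies of one pattern.  The
    factor construction is positive definite by design for loadings < 1.

    Per-state magnitude ``scales`` default to a ladder from 1.0 down to
    0.35: state 1 is the designated "strong" state (largest positive and
    negative correlations; for 5 modules its positive blocks are the motor
    and visual modules, anticorrelated with higher-order modules) and the
    last state is the designated "sparse" state with only faint structure.
    ``strength`` scales all loadings (peak loading = 0.9 x strength, capped
    at 0.92).
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_networks < 2:
        raise ValueError("n_networks must be >= 2")
    sizes = block_structure if block_structure is not None else _default_modules(n_networks)
    if sum(sizes) != n_networks:
        raise ValueError("block structure must sum to n_networks")
    edges = np.cumsum([0] + list(sizes))
    n_mod = len(sizes)
    module = np.zeros(n_networks, dtype=int)
    for m in range(n_mod):
        module[edges[m]:edges[m + 1]] = m

    if scales is None:
        if n_states == 1:
            scales = (1.0,)
        else:
            scales = tuple(1.0 - 0.65 * s / (n_states - 1) for s in range(n_states))
    if len(scales) != n_states:
        raise ValueError("scales length must equal n_states")

    peak = min(0.9 * strength, 0.92)
    covs, labels = [], []
    for s in range(n_states):
        a = peak * scales[s]
        L = np.zeros((n_networks, 2))
        L[module == (2 * s) % n_mod, 0] = a
        if n_mod >= 2:
            L[module == (2 * s + 1) % n_mod, 0] = 0.9 * a
        if n_mod >= 3:
            L[module == (2 * s + 2) % n_mod, 0] = -0.75 * a
        if n_mod >= 4:
            L[module == (2 * s + 3) % n_mod, 1] = 0.8 * a
        R = L @ L.T
        np.fill_diagonal(R, 1.0)  # psi_i = 1 - sum_f L_if^2 on the diagonal
        covs.append(_shrink_to_spd(R, min_eig, f"state {s + 1}"))
        labels.append(f"state {s + 1}")
    return StateModel(covariances=tuple(covs), labels=tuple(labels))


# ---------------------------------------------------------------------------
# Markov utilities
# ---------------------------------------------------------------------------


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    P = np.asarray(P, dtype=float)
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _sample_chain(markov: MarkovSpec, T: int, rng: np.random.Generator) -> np.ndarray:
    k = markov.n_states
    states = np.empty(T, dtype=int)
    states[0] = rng.choice(k, p=markov.initial_probs)
    cum = np.cumsum(markov.transition_matrix, axis=1)
    u = rng.random(T - 1)
    for t in range(1, T):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t - 1], side="right")
    return states


# ---------------------------------------------------------------------------
# Subject / cohort simulation
# ---------------------------------------------------------------------------


def simulate_subject(
    model: StateModel,
    markov: MarkovSpec,
    T: int = 128,
    tr: float = 3.0,
    noise_sd: float = 0.0,
    trend_scale: float = 0.0,
    spike_rate: float = 0.0,
    spike_amplitude: float = 0.0,
    seed: int | np.random.Generator | None = None,
    subject_id: str = "sub-000",
    group: str = "",
    network_names: list[str] | None = None,
) -> tuple[TimecourseSet, GroundTruth]:
    """Simulate one subject's T x N time-course matrix plus ground truth.

    Emission model: y_t ~ N(0, Sigma_{s_t}) with s_t the latent Markov
    chain.  Optional additive components: polynomial trend of orders 1-3
    with coefficients drawn U(-trend_scale, trend_scale) per network,
    sparse spikes of magnitude ``spike_amplitude`` (random sign) on
    Bernoulli(``spike_rate``) cells, and white Gaussian noise.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    if markov.n_states != model.n_states:
        raise ValueError(
            f"dimension mismatch: model has {model.n_states} states, "
            f"Markov spec has {markov.n_states}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    N = model.n_networks

    states = _sample_chain(markov, T, rng)
    chols = [np.linalg.cholesky(c) for c in model.covariances]
    eps = rng.standard_normal((T, N))
    data = np.empty((T, N))
    for s in range(model.n_states):
        idx = states == s
        if np.any(idx):
            data[idx] = eps[idx] @ chols[s].T

    if trend_scale > 0:
        t = np.linspace(-1.0, 1.0, T)
        basis = np.column_stack([t, t**2, t**3])
        coeffs = rng.uniform(-trend_scale, trend_scale, size=(3, N))
        data = data + basis @ coeffs

    spike_positions: list[tuple[int, int]] = []
    if spike_rate > 0 and spike_amplitude != 0:
        mask = rng.random((T, N)) < spike_rate
        signs = np.where(rng.random((T, N)) < 0.5, -1.0, 1.0)
        data = data + mask * signs * spike_amplitude
        spike_positions = [tuple(ix) for ix in np.argwhere(mask)]

    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=(T, N))

    names = network_names or default_network_names(N)
    tc = TimecourseSet(data=data, tr=tr, network_names=list(names), subject_id=subject_id)
    gt = GroundTruth(states=states + 1, group=group, spike_positions=spike_positions)
    return tc, gt


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[list[TimecourseSet], pd.DataFrame, list[GroundTruth]]:
    """Simulate every subject in the cohort. Deterministic given ``spec.seed``.

    Returns (timecourses, manifest, ground truths); the manifest carries
    subject_id, group, age, gender (0 = male, 1 = female), study (0/1) and
    the per-subject child seed, plus clinical columns if requested.
    """
    if not spec.groups:
        raise ValueError("cohort must declare at least one group (may have 0 subjects)")
    ss = np.random.SeedSequence(spec.seed)
    names = default_network_names(spec.state_model.n_networks)

    tcs: list[TimecourseSet] = []
    gts: list[GroundTruth] = []
    rows: list[dict] = []
    covar_rng = np.random.default_rng(ss.spawn(1)[0])
    for g in spec.groups:
        age_mean, age_sd, frac_female, frac_study2 = spec.covariates.get(
            g.name, (76.0, 7.0, 0.33, 0.5)
        )
        children = ss.spawn(g.n_subjects)
        for i in range(g.n_subjects):
            sid = f"{g.name}-{i + 1:03d}"
            child = children[i]
            rng = np.random.default_rng(child)
            tc, gt = simulate_subject(
                spec.state_model,
                g.markov,
                T=spec.T,
                tr=spec.tr,
                noise_sd=spec.noise_sd,
                trend_scale=spec.trend_scale,
                spike_rate=spec.spike_rate,
                spike_amplitude=spec.spike_amplitude,
                seed=rng,
                subject_id=sid,
                group=g.name,
                network_names=names,
            )
            row = {
                "subject_id": sid,
                "group": g.name,
                "age": float(np.clip(covar_rng.normal(age_mean, age_sd), 60.0, 95.0)),
                "gender": int(covar_rng.random() < frac_female),
                "study": int(covar_rng.random() < frac_study2),
                "seed": int(child.generate_state(1, dtype=np.uint32)[0]),
            }
            if spec.clinical:
                row.update(_clinical_scores(g.name, covar_rng))
            tcs.append(tc)
            gts.append(gt)
            rows.append(row)
    manifest = pd.DataFrame(rows)
    return tcs, manifest, gts


_CLINICAL = {
    # (mean, sd) per score per group; NaN -> not administered in that group
    "MMSE": {"HC": (28.9, 1.1), "AD": (21.8, 3.8), "DLB": (22.0, 4.3)},
    "CAMCOG": {"HC": (96.7, 3.2), "AD": (70.3, 13.5), "DLB": (73.3, 13.6)},
    "UPDRS3": {"HC": (1.94, 2.8), "AD": (3.5, 4.0), "DLB": (18.1, 10.0)},
    "CAF": {"AD": (1.0, 2.5), "DLB": (4.8, 4.9)},
    "NPI_hall": {"AD": (0.0, 0.0), "DLB": (1.6, 1.8)},
}


def _clinical_scores(group: str, rng: np.random.Generator) -> dict[str, float]:
    out = {}
    for score, per_group in _CLINICAL.items():
        if group in per_group:
            m, s = per_group[group]
            v = rng.normal(m, s) if s > 0 else m
            v = max(v, 0.0)
            if score == "MMSE":
                v = min(v, 30.0)
            out[score] = round(v, 1)
        else:
            out[score] = np.nan
    return out


# ---------------------------------------------------------------------------
# Study-shaped defaults
# ---------------------------------------------------------------------------

# Group-specific Markov dynamics. Controls split time roughly evenly across
# the three states; both patient groups leave the strongly connected state 1
# faster and enter it less, and the DLB-like group additionally lingers in
# the sparse state 2 (the most common state overall).
_HC_P = np.array([
    [0.92, 0.05, 0.03],
    [0.03, 0.93, 0.04],
    [0.03, 0.05, 0.92],
])
_AD_P = np.array([
    [0.85, 0.09, 0.06],
    [0.02, 0.94, 0.04],
    [0.02, 0.06, 0.92],
])
_DLB_P = np.array([
    [0.84, 0.10, 0.06],
    [0.015, 0.95, 0.035],
    [0.02, 0.06, 0.92],
])


def _markov(P: np.ndarray) -> MarkovSpec:
    return MarkovSpec(initial_probs=stationary_distribution(P), transition_matrix=P)


def default_cohort_spec(seed: int = 0, clinical: bool = True) -> CohortSpec:
    """The study-shaped cohort: 31 HC / 29 AD / 31 DLB subjects, 27 networks,
    128 time points at TR = 3 s, three connectivity states with group-specific
    occupancy (state 1 visited less by the patient groups, sparse state 2
    visited more by the DLB-like group)."""
    model = generate_state_model(n_states=3, n_networks=27, strength=0.6)
    covariates = {
        "HC": (76.4, 7.2, 9 / 31, 16 / 31),
        "AD": (75.2, 8.6, 9 / 29, 16 / 29),
        "DLB": (78.1, 6.7, 12 / 31, 19 / 31),
    }
    return CohortSpec(
        groups=[
            GroupSpec("HC", 31, _markov(_HC_P)),
            GroupSpec("AD", 29, _markov(_AD_P)),
            GroupSpec("DLB", 31, _markov(_DLB_P)),
        ],
        state_model=model,
        T=128,
        tr=3.0,
        noise_sd=0.3,
        trend_scale=0.5,
        spike_rate=0.002,
        spike_amplitude=6.0,
        covariates=covariates,
        clinical=clinical,
        seed=seed,
    )


def well_separated_scenario(n_subjects: int = 30, seed: int = 0) -> CohortSpec:
    """Single-group scenario with strongly separated states and slow switching,
    used for state-recovery checks: strength 0.9 with all three states at
    full magnitude (equally strong, distinctly structured patterns), balanced
    self-transitions 0.97 (mean dwell ~33 TR, 1.5x the default window length,
    so most windows are state-pure), light noise, no trend/spike artifacts."""
    model = generate_state_model(n_states=3, n_networks=27, strength=0.9,
                                 scales=(1.0, 1.0, 1.0))
    P = np.full((3, 3), 0.015)
    np.fill_diagonal(P, 0.97)
    return CohortSpec(
        groups=[GroupSpec("SIM", n_subjects, _markov(P))],
        state_model=model,
        T=128,
        tr=3.0,
        noise_sd=0.2,
        trend_scale=0.0,
        spike_rate=0.0,
        spike_amplitude=0.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Ground-truth helpers and serialization
# ---------------------------------------------------------------------------


def window_state_labels(states: np.ndarray, weights: np.ndarray, step: int = 1) -> np.ndarray:
    """Taper-weighted majority latent label per sliding window.

    ``states`` is a length-T label sequence (any integer coding), ``weights``
    the window taper (length w).  Returns one label per window, the label
    with the largest summed taper weight inside the window.
    """
    states = np.asarray(states)
    w = len(weights)
    T = states.size
    if T < w:
        raise ValueError("sequence shorter than window")
    n_win = (T - w) // step + 1
    labels = np.unique(states)
    out = np.empty(n_win, dtype=states.dtype)
    for i in range(n_win):
        seg = states[i * step:i * step + w]
        mass = [weights[seg == lab].sum() for lab in labels]
        out[i] = labels[int(np.argmax(mass))]
    return out


def write_cohort(
    out_dir: str | Path,
    tcs: list[TimecourseSet],
    manifest: pd.DataFrame,
    gts: list[GroundTruth],
) -> None:
    """Write one TSV per subject, manifest.csv and ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tc in tcs:
        tc.to_tsv(out / f"{tc.subject_id}.tsv")
    manifest.to_csv(out / "manifest.csv", index=False)
    gt_obj = {
        tc.subject_id: {
            "states": [int(s) for s in gt.states],
            "group": gt.group,
            "spike_positions": [[int(a), int(b)] for a, b in gt.spike_positions],
        }
        for tc, gt in zip(tcs, gts)
    }
    (out / "ground_truth.json").write_text(json.dumps(gt_obj))
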