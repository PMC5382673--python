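"""Regime-switching synthetic cohorts with known connectivity states.

The generator emulates a two-group resting-state study: each subject's
component time courses are drawn from a hidden first-order Markov chain over
K connectivity states.  While the chain sits in state k the observation at
each time step is a zero-mean multivariate normal with that state's
correlation matrix, plus independent Gaussian observation noise.  Group
membership sets the per-step probability of leaving the current state, and a
behaviour score is coupled linearly to each subject's true number of regime
switches, so every downstream stage (windowing, state clustering, transition
statistics, behaviour correlations) can be validated against ground truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .panel import MotionParams, TimeCoursePanel, default_subnetwork_labels

_SPD_EPS = 1e-8
_MAX_SPD_REPAIRS = 50


def derive_seed(*parts) -> int:
    """Map an arbitrary tuple of hashables to a stable seed below 2**31."""
    text = ":".join(repr(p) for p in parts)
    digest = hashlib.sha256(text.encode("utf-8")).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class RegimeSwitchingSpec:
    """Full description of a synthetic regime-switching cohort.

    Defaults mirror the emulated study design: 22 subjects per group, 240
    time points at TR = 2 s, 42 components in 7 sub-networks, K = 4
    connectivity states, and a behaviour score coupled to transition counts
    in the high group only.
    """

    n_components: int = 42
    n_blocks: int = 7
    K: int = 4
    T: int = 240
    tr_seconds: float = 2.0
    n_per_group: int = 22
    within_strength: float = 0.6
    between_strength: float = 0.35
    # Observation noise sd; 1/sqrt(2) gives in-state edge SNR (signal
    # variance over noise variance) of 2.
    noise_sd: float = 2.0 ** -0.5
    switch_prob_per_group: dict = field(
        default_factory=lambda: {"high": 0.10, "low": 0.05})
    behavior_coupling: dict = field(
        default_factory=lambda: {"high": 0.8, "low": 0.0})
    behavior_intercept: dict = field(
        default_factory=lambda: {"high": 45.0, "low": 38.0})
    behavior_noise_sd: float = 4.0
    seed: int = 0
    subnetwork_labels: list[str] | None = None
    state_correlations: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if self.T < 2:
            raise ValueError("T must be at least 2")
        for g, p in self.switch_prob_per_group.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"switch probability for {g!r} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.subnetwork_labels is None:
            self.subnetwork_labels = default_subnetwork_labels(
                self.n_components, self.n_blocks)
        if len(self.subnetwork_labels) != self.n_components:
            raise ValueError("subnetwork_labels length != n_components")
        if self.state_correlations is None:
            self.state_correlations = make_state_correlations(
                self.n_components, self.subnetwork_labels, self.K,
                self.within_strength, self.between_strength, seed=self.seed)
        if len(self.state_correlations) != self.K:
            raise ValueError("need one correlation matrix per state")
        for k, R in enumerate(self.state_correlations):
            R = np.asarray(R, float)
            if R.shape != (self.n_components, self.n_components):
                raise ValueError(f"state {k}: wrong correlation matrix shape")
            if not np.allclose(R, R.T, atol=1e-10):
                raise ValueError(f"state {k}: correlation matrix not symmetric")
            if not np.allclose(np.diag(R), 1.0, atol=1e-8):
                raise ValueError(f"state {k}: diagonal must be 1")
            if np.linalg.eigvalsh(R).min() <= 0:
                raise ValueError(f"state {k}: matrix not positive definite")

    @property
    def groups(self) -> list[str]:
        return list(self.switch_prob_per_group)

    @property
    def component_ids(self) -> list[str]:
        return [f"ic{i + 1:02d}" for i in range(self.n_components)]


@dataclass
class GroundTruth:
    """Per-subject hidden-state record emitted alongside the time courses."""

    state_sequence: np.ndarray  # length T, values in 1..K
    transition_count: int
    occupancy: np.ndarray  # length K counts

    def __post_init__(self) -> None:
        self.state_sequence = np.asarray(self.state_sequence, dtype=int)
        self.occupancy = np.asarray(self.occupancy, dtype=int)
        if self.occupancy.sum() != self.state_sequence.size:
            raise ValueError("occupancy must sum to T")
        n_switch = int(np.sum(np.diff(self.state_sequence) != 0))
        if n_switch != self.transition_count:
            raise ValueError("transition_count inconsistent with sequence")


def _nearest_correlation(R: np.ndarray) -> np.ndarray:
    """One eigenvalue-clipping step towards the SPD correlation cone."""
    vals, vecs = np.linalg.eigh(R)
    vals = np.clip(vals, 1e-6, None)
    R = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2


def make_state_correlations(n_components, subnetwork_labels, K,
                            within_strength=0.6, between_strength=0.35,
                            seed=0):
    """Build K distinct block-patterned SPD correlation matrices.

    Each state carries the within-block correlation on a state-specific
    subset of sub-networks (the remaining blocks get half strength) and
    couples a state-specific set of block pairs at ``between_strength``,
    giving visibly different connectivity patterns across states — moderate
    to high correlation within and between sub-networks, as in empirical
    dFC centroids.

    Raises
    ------
    ValueError
        If the requested strengths cannot be repaired into a positive
        definite correlation matrix, or the resulting centroids are not
        distinct (pairwise pattern correlation must stay below 0.8).
    """
    if not -1.0 < within_strength < 1.0 or not -1.0 < between_strength < 1.0:
        raise ValueError("strengths must lie in (-1, 1)")
    labels = list(subnetwork_labels)
    if len(labels) != n_components:
        raise ValueError("subnetwork_labels length != n_components")
    block_names = list(dict.fromkeys(labels))  # preserve order
    if any(labels.count(b) == 0 for b in block_names):
        raise ValueError("blocks must be non-empty")
    B = len(block_names)
    members = {b: np.flatnonzero([l == b for l in labels]) for b in block_names}

    mats = []
    for k in range(K):
        R = np.eye(n_components)
        for bi, b in enumerate(block_names):
            idx = members[b]
            # state-specific subset of blocks carries full within strength
            strength = within_strength if (bi + k) % K != K - 1 \
                else within_strength * 0.5
            for i in idx:
                for j in idx:
                    if i != j:
                        R[i, j] = strength
        for bi in range(B):
            for bj in range(bi + 1, B):
                if (bi + bj + k) % K == 0:
                    ii = members[block_names[bi]]
                    jj = members[block_names[bj]]
                    R[np.ix_(ii, jj)] = between_strength
                    R[np.ix_(jj, ii)] = between_strength
        for _ in range(_MAX_SPD_REPAIRS):
            if np.linalg.eigvalsh(R).min() > _SPD_EPS:
                break
            R = _nearest_correlation(R)
        else:
            raise ValueError(
                "requested strengths too extreme: could not repair to a "
                "positive definite correlation matrix")
        mats.append(R)

    iu = np.triu_indices(n_components, 1)
    for a in range(K):
        for b in range(a + 1, K):
            va, vb = mats[a][iu], mats[b][iu]
            if va.std() > 0 and vb.std() > 0:
                r = np.corrcoef(va, vb)[0, 1]
                if r >= 0.8:
                    raise ValueError(
                        f"states {a} and {b} are not distinct (pattern "
                        f"correlation {r:.2f} >= 0.8)")
    return mats


def _simulate_chain(K: int, T: int, switch_prob: float,
                    rng: np.random.Generator) -> np.ndarray:
    # Leaving moves to a uniform choice among the other K-1 states, i.e. a
    # uniform offset in 1..K-1 (mod K); the chain is then a cumulative sum.
    s0 = rng.integers(0, K)
    leave = rng.random(T - 1) < switch_prob
    offsets = rng.integers(1, K, size=T - 1)
    steps = np.concatenate([[s0], leave * offsets])
    return np.cumsum(steps) % K + 1


def _ground_truth_from_sequence(seq: np.ndarray, K: int) -> GroundTruth:
    occ = np.bincount(seq, minlength=K + 1)[1:]
    return GroundTruth(state_sequence=seq,
                       transition_count=int(np.sum(np.diff(seq) != 0)),
                       occupancy=occ)


def simulate_subject(spec: RegimeSwitchingSpec, group: str,
                     subject_seed: int) -> tuple[TimeCoursePanel, GroundTruth]:
    """Draw one subject's time courses and the hidden-state ground truth."""
    if group not in spec.switch_prob_per_group:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(subject_seed)
    seq = _simulate_chain(spec.K, spec.T, spec.switch_prob_per_group[group],
                          rng)
    chols = [np.linalg.cholesky(R) for R in spec.state_correlations]
    z = rng.standard_normal((spec.T, spec.n_components))
    data = np.empty_like(z)
    for t in range(spec.T):
        data[t] = chols[seq[t] - 1] @ z[t]
    if spec.noise_sd > 0:
        data += spec.noise_sd * rng.standard_normal(data.shape)
    panel = TimeCoursePanel(data=data, tr_seconds=spec.tr_seconds,
                            component_ids=spec.component_ids,
                            subnetwork_labels=list(spec.subnetwork_labels),
                            subject_id="")
    return panel, _ground_truth_from_sequence(seq, spec.K)


def _simulate_motion(T: int, rng: np.random.Generator) -> np.ndarray:
    steps = np.concatenate([
        rng.normal(0.0, 0.02, size=(T, 3)),     # translations, mm
        rng.normal(0.0, 4e-4, size=(T, 3)),     # rotations, radians
    ], axis=1)
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


def simulate_cohort(spec: RegimeSwitchingSpec, include_timecourses: bool = True):
    """Simulate the full two-group cohort.

    Returns a dict with keys ``panels`` (subject_id -> TimeCoursePanel; empty
    when include_timecourses is False), ``motion`` (subject_id ->
    MotionParams), ``sample_sheet`` (pandas DataFrame: subject_id, group,
    score, iq, age, gender) and ``ground_truth`` (subject_id -> GroundTruth).

    ``include_timecourses=False`` draws only the hidden chains, scores and
    covariates — used by power studies that need many cohort replicates but
    no observations.
    """
    import pandas as pd

    if spec.n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")

    panels: dict[str, TimeCoursePanel] = {}
    motion: dict[str, MotionParams] = {}
    truths: dict[str, GroundTruth] = {}
    rows = []
    idx = 0
    for group in spec.groups:
        for j in range(spec.n_per_group):
            idx += 1
            sid = f"sub-{idx:03d}"
            sseed = derive_seed(spec.seed, "subject", group, j)
            if include_timecourses:
                panel, gt = simulate_subject(spec, group, sseed)
                panel.subject_id = sid
                panels[sid] = panel
                motion[sid] = MotionParams(
                    _simulate_motion(spec.T,
                                     np.random.default_rng(sseed + 1)),
                    subject_id=sid)
            else:
                rng = np.random.default_rng(sseed)
                seq = _simulate_chain(spec.K, spec.T,
                                      spec.switch_prob_per_group[group], rng)
                gt = _ground_truth_from_sequence(seq, spec.K)
            truths[sid] = gt
            crng = np.random.default_rng(derive_seed(spec.seed, "covar",
                                                     group, j))
            score = (spec.behavior_intercept[group]
                     + spec.behavior_coupling[group] * gt.transition_count
                     + crng.normal(0.0, spec.behavior_noise_sd))
            rows.append({
                "subject_id": sid,
                "group": group,
                "score": float(score),
                "iq": float(crng.normal(55.0, 4.0)),
                "age": float(crng.normal(19.0, 1.0)),
                "gender": int(j % 2),
            })
    sheet = pd.DataFrame(rows)
    return {"panels": panels, "motion": motion, "sample_sheet": sheet,
            "ground_truth": truths}
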