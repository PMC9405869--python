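"""Synthetic resting-state cohorts with a localized pre/post effect.

Generates node x timepoint signal panels for a paired (pre, post) design:
multivariate Gaussian node signals with a modular block-correlation
structure emulating resting-state functional communities, per-subject
heterogeneity via jitter on the correlation entries, and a controllable
post-session increase in connectivity among a designated target node and
its neighbourhood — the analogue of a focal intervention effect.

Defaults mirror the emulated study: 23 subjects, 116 nodes (8 communities),
260 timepoints per session. No temporal autocorrelation is modelled: the
downstream pipeline consumes Pearson correlations only, for which the
ordering of timepoints is irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "TimeSeriesPanel",
    "build_population_covariance",
    "community_labels",
    "neighbourhood_nodes",
    "simulate_panel",
    "write_panel",
    "read_panel",
]

#: effect_delta giving a standardized Local-Efficiency AUC difference near
#: the d ~ 0.9 scale of the emulated intervention (calibrated by simulation
#: on the replicate-study cohort; see docs/methods.md)
CALIBRATED_EFFECT_DELTA = 0.15

_EIG_FLOOR = 1e-8


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level generator settings; all randomness derives from ``seed``."""

    n_subjects: int = 23
    n_nodes: int = 116
    n_timepoints: int = 260
    n_communities: int = 8
    within_community_corr: float = 0.4
    between_community_corr: float = 0.08
    target_node: int = 0
    neighbourhood_size: int = 10
    effect_delta: float = CALIBRATED_EFFECT_DELTA
    subject_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_timepoints) < 1 or self.n_nodes < 3:
            raise ValueError("degenerate cohort dimensions")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 timepoints")
        if not (0 <= self.between_community_corr < 1):
            raise ValueError("between_community_corr must lie in [0, 1)")
        if not (0 <= self.within_community_corr < 1):
            raise ValueError("within_community_corr must lie in [0, 1)")
        if self.within_community_corr <= self.between_community_corr:
            raise ValueError("within_community_corr must exceed between_community_corr")
        if not (0 <= self.effect_delta < 1):
            raise ValueError("effect_delta must lie in [0, 1)")
        if self.effect_delta + self.within_community_corr >= 1:
            raise ValueError("effect_delta + within_community_corr must stay below 1")
        if not (0 <= self.target_node < self.n_nodes):
            raise ValueError("target_node out of range")
        if self.neighbourhood_size < 2:
            raise ValueError("neighbourhood_size must be >= 2")
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be nonnegative")
        if self.n_communities < 1 or self.n_communities > self.n_nodes:
            raise ValueError("n_communities out of range")


@dataclass
class TimeSeriesPanel:
    """Per-(subject, session) node x timepoint signal matrices."""

    subjects: list[str]
    sessions: tuple[str, str]
    series: dict[tuple[str, str], np.ndarray]

    def __post_init__(self) -> None:
        shapes = {m.shape[0] for m in self.series.values()}
        if len(shapes) > 1:
            raise ValueError("all matrices must share one node count")
        for (sub, ses), m in self.series.items():
            if m.shape[1] < 3:
                raise ValueError(f"{sub}/{ses}: need at least 3 timepoints")
            if np.any(m.std(axis=1) == 0):
                raise ValueError(f"{sub}/{ses}: constant node signal")
        missing = [
            (sub, ses)
            for sub in self.subjects
            for ses in self.sessions
            if (sub, ses) not in self.series
        ]
        if missing:
            raise ValueError(f"missing session matrices: {missing}")

    @property
    def n_nodes(self) -> int:
        return next(iter(self.series.values())).shape[0]


def community_labels(config: SyntheticConfig) -> np.ndarray:
    """Community index per node: contiguous near-equal blocks."""
    labels = np.empty(config.n_nodes, dtype=int)
    for ci, block in enumerate(
        np.array_split(np.arange(config.n_nodes), config.n_communities)
    ):
        labels[block] = ci
    return labels


def neighbourhood_nodes(config: SyntheticConfig) -> np.ndarray:
    """The designated neighbours of the target node (target excluded).

    The first ``neighbourhood_size`` members of the target's community other
    than the target itself; the injected effect raises correlations among
    {target} ∪ this set.
    """
    labels = community_labels(config)
    members = np.nonzero(labels == labels[config.target_node])[0]
    others = members[members != config.target_node]
    if others.size < config.neighbourhood_size:
        raise ValueError(
            f"target community has only {others.size} other members; "
            f"neighbourhood_size={config.neighbourhood_size} does not fit"
        )
    return others[: config.neighbourhood_size]


def _repair_correlation(mat: np.ndarray, floor: float = _EIG_FLOOR) -> np.ndarray:
    """Nearest-PD style repair: clip eigenvalues at ``floor``, re-standardize."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.max() <= floor:
        raise ValueError("correlation matrix not repairable: all eigenvalues at/below floor")
    clipped = np.clip(vals, floor, None)
    fixed = (vecs * clipped) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2.0


def build_population_covariance(config: SyntheticConfig) -> np.ndarray:
    """Block correlation matrix: ``within`` inside communities, ``between``
    elsewhere, unit diagonal; repaired to positive definite if needed."""
    labels = community_labels(config)
    same = labels[:, None] == labels[None, :]
    cov = np.where(same, config.within_community_corr, config.between_community_corr)
    np.fill_diagonal(cov, 1.0)
    if np.linalg.eigvalsh(cov).min() <= _EIG_FLOOR:
        cov = _repair_correlation(cov)
    return cov


def _subject_ids(n: int) -> list[str]:
    return [f"sub-{i + 1:03d}" for i in range(n)]


def simulate_panel(config: SyntheticConfig) -> TimeSeriesPanel:
    """Draw the full paired cohort.

    Per subject, a jittered copy of the population correlation matrix is the
    "pre" covariance; the "post" covariance additionally has ``effect_delta``
    added to every off-diagonal entry among the target node and its
    designated neighbourhood. The jitter is shared between a subject's two
    sessions, so with ``effect_delta = 0`` pre and post are draws from the
    same distribution. Bit-reproducible from ``config.seed``.
    """
    base = build_population_covariance(config)
    effect_nodes = np.concatenate(([config.target_node], neighbourhood_nodes(config)))
    root = np.random.SeedSequence(config.seed)
    subjects = _subject_ids(config.n_subjects)
    series: dict[tuple[str, str], np.ndarray] = {}
    for sub_id, child in zip(subjects, root.spawn(config.n_subjects)):
        jitter_rng, pre_rng, post_rng = (
            np.random.default_rng(s) for s in child.spawn(3)
        )
        jit = jitter_rng.normal(0.0, config.subject_noise_sd, size=base.shape)
        jit = np.triu(jit, 1)
        jit = jit + jit.T
        subj_corr = np.clip(base + jit, -0.999, 0.999)
        np.fill_diagonal(subj_corr, 1.0)

        post_corr = subj_corr.copy()
        if config.effect_delta > 0:
            block = np.ix_(effect_nodes, effect_nodes)
            post_corr[block] = np.clip(post_corr[block] + config.effect_delta, -0.999, 0.999)
            np.fill_diagonal(post_corr, 1.0)

        for ses, corr, rng in (
            ("pre", subj_corr, pre_rng),
            ("post", post_corr, post_rng),
        ):
            chol = np.linalg.cholesky(_repair_correlation(corr))
            z = rng.standard_normal((config.n_nodes, config.n_timepoints))
            series[(sub_id, ses)] = chol @ z
    return TimeSeriesPanel(subjects=subjects, sessions=("pre", "post"), series=series)


def write_panel(panel: TimeSeriesPanel, out_dir: str | Path) -> Path:
    """Write one TSV matrix per (subject, session) plus a manifest CSV.

    Matrices have rows = nodes, columns = timepoints, no header. Returns the
    manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sub in panel.subjects:
        for ses in panel.sessions:
            fname = f"{sub}_ses-{ses}.tsv"
            np.savetxt(out_dir / fname, panel.series[(sub, ses)], delimiter="\t")
            rows.append({"subject": sub, "session": ses, "path": fname})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_panel(manifest_path: str | Path, sessions: tuple[str, str] = ("pre", "post")) -> TimeSeriesPanel:
    """Load a panel from a manifest CSV (columns subject, session, path).

    Relative paths resolve against the manifest's directory. Every subject
    must have both sessions; a missing file is reported with its subject.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    required = {"subject", "session", "path"}
    if not required.issubset(table.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    series = {}
    for row in table.itertuples(index=False):
        path = Path(row.path)
        if not path.is_absolute():
            path = manifest_path.parent / path
        if not path.exists():
            raise FileNotFoundError(
                f"missing matrix for subject {row.subject} session {row.session}: {path}"
            )
        series[(str(row.subject), str(row.session))] = np.loadtxt(path, delimiter="\t")
    subjects = list(dict.fromkeys(str(s) for s in table["subject"]))
    return TimeSeriesPanel(subjects=subjects, sessions=sessions, series=series)
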