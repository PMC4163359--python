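"""Synthetic multi-site resting-state cohorts with planted group effects.

This module emulates the structure of a multi-site paediatric resting-state
fMRI release after parcellation: per subject, a timepoints x ROIs matrix of
BOLD-like signals; per cohort, several acquisition sites with unequal group
sizes (typically developing controls, ADHD-inattentive, ADHD-combined),
site-specific observation noise, and between-group connectivity differences
concentrated on a small set of "discriminative" nodes.

The latent correlation structure is block-modular: ROIs are partitioned into
contiguous modules (a stand-in for resting-state networks) with constant
within-module and between-module correlation, which keeps the matrix
positive semidefinite in closed form.  A group effect is an additive shift
of every correlation incident to the chosen effect nodes, followed by a
projection back onto the cone of unit-diagonal PSD matrices.  Subjects are
i.i.d. zero-mean multivariate normal draws from their group's latent
correlation matrix plus isotropic observation noise; the noise enters the
covariance (``cov + sd^2 I``) so the subject-level target correlation stays
analytically known (attenuated by ``1/(1 + sd^2)`` on unit-variance nodes).

Nothing here models haemodynamics, temporal autocorrelation, or motion; see
``docs/methods.md`` for what that implies about downstream tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "GROUP_EFFECT_SCALE",
    "SiteSpec",
    "CohortSpec",
    "SubjectRecord",
    "default_sites",
    "make_base_covariance",
    "apply_group_effect",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "cohort_spec_to_dict",
    "cohort_spec_from_dict",
]

GROUPS = ("control", "inattentive", "combined")

#: Multiplier applied to ``CohortSpec.effect_size`` per group: controls sit at
#: the base connectivity, the combined presentation carries the full planted
#: shift, and the inattentive group is halfway between.  This makes both the
#: control-vs-ADHD and the subtype task discriminable from one knob.
GROUP_EFFECT_SCALE = {"control": 0.0, "inattentive": 0.5, "combined": 1.0}

_PSD_TOL = 1e-8


@dataclass(frozen=True)
class SiteSpec:
    """One acquisition site: group counts, noise level, scan length."""

    site_id: str
    n_per_group: dict
    noise_sd: float = 0.5
    n_timepoints: int | None = None

    def validate(self, groups: tuple[str, ...]) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"site {self.site_id!r}: noise_sd must be >= 0")
        for g, k in self.n_per_group.items():
            if g not in groups:
                raise ValueError(f"site {self.site_id!r}: unknown group {g!r}")
            if k < 0:
                raise ValueError(f"site {self.site_id!r}: negative count for {g!r}")
        if self.n_timepoints is not None and self.n_timepoints < 3:
            raise ValueError(f"site {self.site_id!r}: need at least 3 timepoints")


def default_sites() -> tuple[SiteSpec, ...]:
    """Five sites with unequal group sizes, 609 subjects in total.

    The per-site control / inattentive / combined split mirrors a public
    multi-site ADHD release: 340 controls, 159 inattentive, 110 combined,
    with one site (``ohsu``) approximately balanced between patients and
    controls and one (``neuroimage``) having very few combined subjects.
    Scan lengths and noise levels differ per site to emulate heterogeneous
    acquisition protocols.
    """
    return (
        SiteSpec("peking", {"control": 116, "inattentive": 56, "combined": 19}, 0.5, 232),
        SiteSpec("kki", {"control": 61, "inattentive": 21, "combined": 16}, 0.6, 120),
        SiteSpec("neuroimage", {"control": 23, "inattentive": 18, "combined": 7}, 0.7, 180),
        SiteSpec("nyu", {"control": 98, "inattentive": 44, "combined": 53}, 0.8, 172),
        SiteSpec("ohsu", {"control": 42, "inattentive": 20, "combined": 15}, 0.4, 104),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; the generator's one input."""

    n_rois: int = 400
    n_timepoints: int = 150  # fallback for sites that leave theirs unset
    sites: tuple[SiteSpec, ...] = field(default_factory=default_sites)
    groups: tuple[str, ...] = GROUPS
    n_modules: int = 8
    within_module_corr: float = 0.35
    between_module_corr: float = 0.05
    effect_nodes: tuple[int, ...] = tuple(range(0, 400, 20))
    effect_size: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_rois < 1:
            raise ValueError("n_rois must be positive")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 timepoints")
        for g in self.groups:
            if g not in GROUP_EFFECT_SCALE:
                raise ValueError(f"unknown group label {g!r}")
        for node in self.effect_nodes:
            if not 0 <= node < self.n_rois:
                raise ValueError(f"effect node {node} outside 0..{self.n_rois - 1}")
        if not -1.0 < self.effect_size < 1.0:
            raise ValueError("effect_size must lie in (-1, 1)")
        for site in self.sites:
            site.validate(self.groups)


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's ROI time series with its site and group label."""

    subject_id: str
    site: str
    group: str
    timeseries: np.ndarray

    def __post_init__(self):
        ts = np.asarray(self.timeseries, dtype=float)
        if ts.ndim != 2:
            raise ValueError("timeseries must be a 2-d (timepoints x ROIs) matrix")
        if ts.shape[0] < 3:
            raise ValueError("timeseries needs at least 3 timepoints")
        if not np.isfinite(ts).all():
            raise ValueError("timeseries contains non-finite values")
        object.__setattr__(self, "timeseries", ts)


def make_base_covariance(
    n_rois: int,
    n_modules: int,
    within_module_corr: float,
    between_module_corr: float,
) -> np.ndarray:
    """Block-constant latent correlation matrix over contiguous modules.

    Module ``i`` of ``n_modules`` owns ROIs ``[i*b, (i+1)*b)`` with
    ``b = n_rois // n_modules``; the remainder goes to the last module.
    Same-module pairs get ``within_module_corr``, all other pairs
    ``between_module_corr``, the diagonal is 1.  For
    ``0 <= between <= within < 1`` the result is positive semidefinite
    (it decomposes into a nonnegative multiple of the all-ones matrix,
    nonnegative block one-matrices, and a positive multiple of I).
    """
    within, between = float(within_module_corr), float(between_module_corr)
    if not (0.0 <= between <= within < 1.0):
        raise ValueError(
            "parameters violate 0 <= between_module_corr <= within_module_corr < 1; "
            "the block-constant matrix would not be a valid (PSD) correlation matrix"
        )
    if not 1 <= n_modules <= n_rois:
        raise ValueError("n_modules must lie in 1..n_rois")
    cov = np.full((n_rois, n_rois), between)
    block = n_rois // n_modules
    for m in range(n_modules):
        lo = m * block
        hi = (m + 1) * block if m < n_modules - 1 else n_rois
        cov[lo:hi, lo:hi] = within
    np.fill_diagonal(cov, 1.0)
    return cov


def _check_correlation(mat: np.ndarray) -> None:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("matrix is not symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
        raise ValueError("matrix does not have a unit diagonal")


def apply_group_effect(
    base: np.ndarray,
    effect_nodes,
    effect_size: float,
) -> np.ndarray:
    """Shift all correlations incident to ``effect_nodes`` by ``effect_size``.

    Off-diagonal entries in the rows/columns of any effect node are shifted
    once (also when both endpoints are effect nodes), clipped to
    [-0.99, 0.99], and the result is projected back to a valid correlation
    matrix: eigenvalues clipped at zero, then re-standardized to a unit
    diagonal.  ``effect_size == 0`` returns ``base`` unchanged (exactly).
    """
    base = np.asarray(base, dtype=float)
    _check_correlation(base)
    nodes = np.asarray(sorted({int(i) for i in effect_nodes}), dtype=int)
    if effect_size == 0:
        return base.copy()
    if nodes.size == 0:
        warnings.warn("nonzero effect_size with empty effect_nodes: no-op", stacklevel=2)
        return base.copy()
    n = base.shape[0]
    if nodes.min() < 0 or nodes.max() >= n:
        raise ValueError("effect node index outside the matrix")
    incident = np.zeros((n, n), dtype=bool)
    incident[nodes, :] = True
    incident[:, nodes] = True
    np.fill_diagonal(incident, False)
    shifted = base.copy()
    shifted[incident] = np.clip(shifted[incident] + float(effect_size), -0.99, 0.99)
    # project to nearest PSD (eigenvalue clipping), then back to unit diagonal
    w, v = np.linalg.eigh(shifted)
    psd = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.sqrt(np.clip(np.diag(psd), 1e-12, None))
    out = psd / d[:, None] / d[None, :]
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return out


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Square-root factor F with F F^T = cov (eigh-based; tolerates singular)."""
    w, v = np.linalg.eigh(cov)
    if w.min() < -_PSD_TOL * max(1.0, float(w.max())):
        raise ValueError("covariance is not positive semidefinite")
    return v * np.sqrt(np.clip(w, 0.0, None))


def _sample_timeseries(factor: np.ndarray, n_timepoints: int, rng: np.random.Generator) -> np.ndarray:
    return rng.standard_normal((n_timepoints, factor.shape[0])) @ factor.T


def simulate_subject(cov: np.ndarray, n_timepoints: int, noise_sd: float, seed) -> np.ndarray:
    """Draw one subject's (timepoints x ROIs) series from N(0, cov + sd^2 I).

    A fixed ``seed`` gives bit-identical output.  ``seed`` may be an int or a
    ``numpy.random.SeedSequence``.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("cov must be square")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("cov must be symmetric")
    if n_timepoints < 3:
        raise ValueError("need at least 3 timepoints")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    total = cov + noise_sd**2 * np.eye(cov.shape[0])
    factor = _psd_factor(total)
    rng = np.random.default_rng(seed)
    return _sample_timeseries(factor, int(n_timepoints), rng)


def _subject_seed(master_seed: int, site_index: int, subject_index: int) -> np.random.SeedSequence:
    # counter-based: one master seed, keyed by (site, subject-within-site)
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(site_index, subject_index))


def simulate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate one :class:`SubjectRecord` per subject of every site/group.

    Subject order is site-major, then group in ``spec.groups`` order.
    Per-subject seeds derive deterministically from ``spec.seed`` and the
    (site, subject) counters, so the cohort is bit-reproducible.
    """
    spec.validate()
    total = sum(site.n_per_group.get(g, 0) for site in spec.sites for g in spec.groups)
    if total == 0:
        raise ValueError("cohort has zero subjects")
    base = make_base_covariance(
        spec.n_rois, spec.n_modules, spec.within_module_corr, spec.between_module_corr
    )
    group_corr = {
        g: apply_group_effect(base, spec.effect_nodes, spec.effect_size * GROUP_EFFECT_SCALE[g])
        for g in spec.groups
    }
    records: list[SubjectRecord] = []
    eye = np.eye(spec.n_rois)
    for site_index, site in enumerate(spec.sites):
        n_t = site.n_timepoints if site.n_timepoints is not None else spec.n_timepoints
        factors = {
            g: _psd_factor(group_corr[g] + site.noise_sd**2 * eye)
            for g in spec.groups
            if site.n_per_group.get(g, 0) > 0
        }
        subject_index = 0
        for g in spec.groups:
            for k in range(site.n_per_group.get(g, 0)):
                rng = np.random.default_rng(_subject_seed(spec.seed, site_index, subject_index))
                ts = _sample_timeseries(factors[g], n_t, rng)
                records.append(
                    SubjectRecord(f"{site.site_id}-{g}-{k:03d}", site.site_id, g, ts)
                )
                subject_index += 1
    return records


# ---------------------------------------------------------------------------
# on-disk cohort format: a CSV manifest plus one plain-text matrix per subject

def write_cohort(records: list[SubjectRecord], out_dir) -> Path:
    """Write time-series files plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    ts_dir = out_dir / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        rel = Path("timeseries") / f"{rec.subject_id}.txt"
        np.savetxt(out_dir / rel, rec.timeseries, fmt="%.10g")
        rows.append(
            {"subject_id": rec.subject_id, "site": rec.site, "group": rec.group,
             "timeseries_path": rel.as_posix()}
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path) -> list[SubjectRecord]:
    """Load a cohort written by :func:`write_cohort` (or hand-assembled)."""
    manifest_path = Path(manifest_path)
    frame = pd.read_csv(manifest_path)
    required = {"subject_id", "site", "group", "timeseries_path"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    root = manifest_path.parent
    records = []
    for row in frame.itertuples(index=False):
        ts = np.loadtxt(root / row.timeseries_path, ndmin=2)
        records.append(SubjectRecord(str(row.subject_id), str(row.site), str(row.group), ts))
    return records


def cohort_spec_to_dict(spec: CohortSpec) -> dict:
    return {
        "n_rois": spec.n_rois,
        "n_timepoints": spec.n_timepoints,
        "groups": list(spec.groups),
        "n_modules": spec.n_modules,
        "within_module_corr": spec.within_module_corr,
        "between_module_corr": spec.between_module_corr,
        "effect_nodes": list(spec.effect_nodes),
        "effect_size": spec.effect_size,
        "seed": spec.seed,
        "sites": [
            {"site_id": s.site_id, "n_per_group": dict(s.n_per_group),
             "noise_sd": s.noise_sd, "n_timepoints": s.n_timepoints}
            for s in spec.sites
        ],
    }


def cohort_spec_from_dict(data: dict) -> CohortSpec:
    data = dict(data)
    sites = data.pop("sites", None)
    kwargs = {}
    for key in ("n_rois", "n_timepoints", "n_modules", "within_module_corr",
                "between_module_corr", "effect_size", "seed"):
        if key in data:
            kwargs[key] = data[key]
    if "groups" in data:
        kwargs["groups"] = tuple(data["groups"])
    if "effect_nodes" in data:
        kwargs["effect_nodes"] = tuple(int(i) for i in data["effect_nodes"])
    if sites is not None:
        kwargs["sites"] = tuple(
            SiteSpec(
                site_id=s["site_id"],
                n_per_group=dict(s["n_per_group"]),
                noise_sd=s.get("noise_sd", 0.5),
                n_timepoints=s.get("n_timepoints"),
            )
            for s in sites
        )
    spec = CohortSpec(**kwargs)
    spec.validate()
    return spec
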