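"""Synthetic cohorts and voxel phantoms.

Every input the pipeline needs can be generated here, so all stages are
testable without any acquired data.

Cohorts emulate the source study's design: a small amyloid-negative group
(n=6) and amyloid-positive group (n=9), two hemisphere values per subject
with intra-subject correlation rho, and programmed group effects expressed
as target Hedge's g per (measure, lobe) cell.  The default effect table
programs the reported directions and magnitudes: SUVR strongly increased in
the positive group everywhere, the exchange rate Rx decreased in the
temporal lobe (g = -0.86), and the semisolid R1s decreased in the frontal /
parietal / temporal lobes (g = -0.78 / -0.81 / -0.94); m0s and cortical
thickness carry no programmed effect.  Control means and SDs are
literature-plausible placeholders (the source figures print no group
means/SDs), except T2s's ~10 µs order of magnitude.

Generative model per (measure, lobe): hemisphere observation
    h = mu + delta_group + sigma * (sqrt(rho) z_subject + sqrt(1-rho) z_hemi),
with delta = g * sigma in the positive group, so the programmed g targets
the pooled-hemisphere observations.  Constituent ROI means scatter tightly
around the lobe value and carry chi-squared-distributed sample variances, so
inverse-variance aggregation is exercised end to end.

Phantoms are small labeled voxel grids with per-tissue qMT parameters;
fingerprints are simulated per voxel, complex circular Gaussian noise is
added, and the result is optionally compressed to subspace coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .atlas import LobeMap
from .spin_model import QMTParams, SequenceSchedule, simulate_fingerprint
from .subspace import SubspaceBasis, compress
from .utils import child_seed, snr_of, spec_hash

#: control-group lobar means and between-observation SDs (placeholders;
#: units: m0s fraction, Rx 1/s, R1s 1/s, SUVR ratio, thickness mm)
DEFAULT_CONTROL = {
    "m0s": (0.10, 0.012),
    "Rx": (55.0, 7.0),
    "R1s": (2.0, 0.25),
    "SUVR": (1.00, 0.06),
    "thickness": (2.5, 0.12),
}

#: programmed group effects (target Hedge's g) per (measure, lobe)
DEFAULT_EFFECTS = {
    ("SUVR", "frontal"): 2.5, ("SUVR", "parietal"): 2.5,
    ("SUVR", "temporal"): 2.5, ("SUVR", "occipital"): 2.5,
    ("Rx", "temporal"): -0.86,
    ("R1s", "frontal"): -0.78, ("R1s", "parietal"): -0.81,
    ("R1s", "temporal"): -0.94,
}


@dataclass
class CohortSpec:
    """Study-design parameters for a synthetic cohort."""

    n_neg: int = 6
    n_pos: int = 9
    control: dict = field(default_factory=lambda: dict(DEFAULT_CONTROL))
    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    rho: float = 0.7
    #: ROI-level scatter around the lobe value, as a fraction of sigma
    roi_scatter_frac: float = 0.1
    #: within-ROI per-sample SD as a fraction of sigma, and samples per ROI
    within_roi_sd_frac: float = 1.0
    n_samples_per_roi: int = 200
    #: optional linear coupling of SUVR to the subject's Rx/R1s deviations
    suvr_coupling: dict = field(default_factory=dict)
    heavy_tails: bool = False  # t(5) subject effects instead of Gaussian
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neg < 2 or self.n_pos < 2:
            raise ValueError("group sizes must be >= 2")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        for m, (mu, sd) in self.control.items():
            if sd <= 0:
                raise ValueError(f"SD for {m} must be positive")

    def hash(self) -> str:
        return spec_hash(asdict(self))


def _draw(rng, size, heavy):
    if heavy:
        return rng.standard_t(5, size=size) / math.sqrt(5.0 / 3.0)
    return rng.standard_normal(size=size)


def _primary_lobes(lobemap: LobeMap) -> list[str]:
    """Lobes whose ROI sets are mutually disjoint (the generative units);
    composites such as the AD signature inherit from their members."""
    names = list(lobemap.lobe_names)
    primary = []
    covered: set[str] = set()
    for name in names:
        rois = set(lobemap.members(name))
        if rois & covered:
            continue
        primary.append(name)
        covered |= rois
    return primary


def implied_composite_g(spec: "CohortSpec", lobemap: LobeMap, composite: str,
                        measure: str) -> float:
    """Effect size a composite lobe inherits from its members' primary lobes.

    With equal member weights, the composite value is sum_L f_L h_L over
    primary lobes L (f_L the member fraction), so the implied standardized
    shift is sum_L f_L g_L / sqrt(sum_L f_L^2).  ROI scatter and the
    chi-squared weight jitter are neglected (both are second order at the
    default settings).
    """
    primary = _primary_lobes(lobemap)
    roi_to_lobe = {r: L for L in primary for r in lobemap.members(L)}
    members = lobemap.members(composite)
    counts: dict[str, int] = {}
    for r in members:
        L = roi_to_lobe.get(r)
        if L is None:
            raise ValueError(f"composite member {r!r} is in no primary lobe")
        counts[L] = counts.get(L, 0) + 1
    f = np.array([counts.get(L, 0) for L in primary], float) / len(members)
    g = np.array([float(spec.effects.get((measure, L), 0.0)) for L in primary])
    denom = math.sqrt(float(np.sum(f**2)))
    return float(np.sum(f * g) / denom)


def generate_cohort(spec: CohortSpec, lobemap: LobeMap | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format ROI measurement table plus the ground-truth effect table.

    Hemisphere lobar values are drawn per (measure, primary lobe); each ROI
    carries its primary lobe's value plus a small scatter, so every
    (subject, hemisphere, roi, measure) row is unique and composite lobes
    (AD signature) inherit their effect from the constituent ROIs.  Effects
    programmed directly on a composite are rejected — program its primary
    lobes instead.  Deterministic per spec.seed (byte-identical tables).
    The ground truth lists the programmed g per primary lobe and the implied
    g for composites.
    """
    lobemap = lobemap or LobeMap()
    primary = _primary_lobes(lobemap)
    composites = [n for n in lobemap.lobe_names if n not in primary]
    for (meas, lobe) in spec.effects:
        if lobe in composites:
            raise ValueError(
                f"effect programmed on composite lobe {lobe!r}; program its "
                f"primary lobes instead (implied g is reported in the truth table)")
    rng = np.random.default_rng(np.random.SeedSequence(
        [spec.seed & 0x7FFFFFFF, 0xC0_0947]))
    subjects = ([(f"neg{i:02d}", "Abeta_neg") for i in range(spec.n_neg)]
                + [(f"pos{i:02d}", "Abeta_pos") for i in range(spec.n_pos)])
    n_sub = len(subjects)
    measures = list(spec.control)
    frames = []
    truth = []
    # subject-level standardized deviations, reused for SUVR coupling
    latent: dict[tuple, np.ndarray] = {}
    hemis = ("left", "right")
    for meas in measures:
        mu, sigma = spec.control[meas]
        for lobe in primary:
            g = float(spec.effects.get((meas, lobe), 0.0))
            truth.append({"measure": meas, "lobe": lobe, "g": g, "mu": mu,
                          "sigma": sigma, "rho": spec.rho, "implied": False})
            members = lobemap.members(lobe)
            R = len(members)
            delta = np.array([g * sigma if grp == "Abeta_pos" else 0.0
                              for _, grp in subjects])
            zs = _draw(rng, n_sub, spec.heavy_tails)
            latent[(meas, lobe)] = zs
            if meas == "SUVR" and spec.suvr_coupling:
                for src, kappa in spec.suvr_coupling.items():
                    if (src, lobe) in latent:
                        delta = delta + kappa * latent[(src, lobe)] * sigma
            zh = _draw(rng, (n_sub, 2), spec.heavy_tails)
            h = (mu + delta[:, None]
                 + sigma * (math.sqrt(spec.rho) * zs[:, None]
                            + math.sqrt(1 - spec.rho) * zh))  # (subjects, hemis)
            sd_roi = spec.roi_scatter_frac * sigma
            sd_w = spec.within_roi_sd_frac * sigma
            n = spec.n_samples_per_roi
            roi_means = h[:, :, None] + sd_roi * rng.standard_normal((n_sub, 2, R))
            s2 = sd_w**2 * rng.chisquare(n - 1, size=(n_sub, 2, R)) / (n - 1)
            frames.append(pd.DataFrame({
                "subject": np.repeat([s for s, _ in subjects], 2 * R),
                "group": np.repeat([grp for _, grp in subjects], 2 * R),
                "hemisphere": np.tile(np.repeat(hemis, R), n_sub),
                "roi": np.tile(members, 2 * n_sub),
                "measure": meas,
                "mean": roi_means.ravel(),
                "sample_variance": s2.ravel(),
                "n_samples": n,
            }))
        for comp in composites:
            truth.append({"measure": meas, "lobe": comp,
                          "g": implied_composite_g(spec, lobemap, comp, meas),
                          "mu": mu, "sigma": sigma, "rho": spec.rho,
                          "implied": True})
    table = pd.concat(frames, ignore_index=True)
    table.attrs["seed"] = spec.seed
    table.attrs["spec_hash"] = spec.hash()
    return table, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# voxel phantoms
# ---------------------------------------------------------------------------

#: default tissue classes (label -> qMT parameters); label 0 is background
DEFAULT_TISSUES = {
    1: QMTParams(m0s=0.20, R1f=0.40, R2f=13.0, Rx=70.0, R1s=3.0, T2s=12e-6),  # WM-like
    2: QMTParams(m0s=0.10, R1f=0.60, R2f=17.0, Rx=50.0, R1s=2.5, T2s=10e-6),  # GM-like
    3: QMTParams(m0s=0.05, R1f=0.90, R2f=22.0, Rx=20.0, R1s=1.0, T2s=8e-6),   # mixed/CSF-adjacent
}


@dataclass
class PhantomSpec:
    """Small labeled grid with per-tissue parameters and noise level."""

    shape: tuple = (8, 8, 8)
    tissues: dict = field(default_factory=lambda: dict(DEFAULT_TISSUES))
    noise_sd: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.tissues:
            raise ValueError("need at least one tissue class")

    def default_labels(self) -> np.ndarray:
        """Concentric boxes of the tissue labels over the grid (0 outside)."""
        labels = np.zeros(self.shape, int)
        keys = sorted(self.tissues)
        nx, ny, nz = self.shape
        margin = max(1, min(self.shape) // 8)
        sl = tuple(slice(margin, s - margin) for s in self.shape)
        core = np.zeros(self.shape, bool)
        core[sl] = True
        idx = np.indices(self.shape)[0]  # split the core into slabs along x
        inner = idx[sl]
        edges = np.linspace(inner.min(), inner.max() + 1, len(keys) + 1)
        for k, key in enumerate(keys):
            band = core & (idx >= edges[k]) & (idx < edges[k + 1])
            labels[band] = key
        return labels

    def hash(self) -> str:
        d = asdict(self)
        d["tissues"] = {k: list(v.as_array()) for k, v in self.tissues.items()}
        return spec_hash(d)


def generate_phantom(spec: PhantomSpec, schedule: SequenceSchedule,
                     basis: SubspaceBasis | None = None,
                     labels: np.ndarray | None = None):
    """Simulate a noisy coefficient-image phantom.

    Returns (labels, truth_maps, data, meta): integer label volume, dict of
    six ground-truth parameter maps (NaN outside tissue), complex 4-D array
    (X, Y, Z, r or T) of noisy per-voxel data, and a provenance dict with
    the seed, spec hash and realized SNR per tissue.
    """
    if labels is None:
        labels = spec.default_labels()
    labels = np.asarray(labels, int)
    if labels.shape != tuple(spec.shape):
        raise ValueError("label volume shape does not match spec")
    present = [k for k in sorted(spec.tissues) if np.any(labels == k)]
    clean = {}
    for k in present:
        fp = simulate_fingerprint(spec.tissues[k], schedule)
        clean[k] = compress(fp, basis) if basis is not None else fp
    width = len(next(iter(clean.values()))) if clean else (
        basis.rank if basis is not None else schedule.n_reps)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF,
                                                        0x9A_0713]))
    data = np.zeros(spec.shape + (width,), complex)
    from .spin_model import PARAM_NAMES
    truth = {n: np.full(spec.shape, np.nan) for n in PARAM_NAMES}
    noise = spec.noise_sd * (rng.standard_normal(data.shape)
                            + 1j * rng.standard_normal(data.shape))
    snrs = {}
    for k in present:
        vox = labels == k
        data[vox] = clean[k]
        for n in PARAM_NAMES:
            truth[n][vox] = getattr(spec.tissues[k], n)
        if spec.noise_sd > 0:
            snrs[k] = snr_of(clean[k], spec.noise_sd)
    data += noise
    data[labels == 0] = noise[labels == 0]
    meta = {"seed": spec.seed, "spec_hash": spec.hash(), "snr_per_tissue": snrs,
            "noise_sd": spec.noise_sd}
    return labels, truth, data, meta
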