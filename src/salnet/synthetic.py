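"""Synthetic MRI cohorts with planted, recoverable structure.

The generator emulates the statistical skeleton a severity-classification /
saliency-correlation analysis assumes, on a desk-scale grid:

* a two-hemisphere parcellation with mirror-placed cortical blobs in an
  outer shell, subcortical blobs in the core, and midline structures
  (brain-stem / fornix analogues) that are not split across hemispheres;
* severity-dependent intensity/texture perturbations planted in designated
  region sets ("blocks"), one block per latent effect factor, so that
  regions in the same block share a latent magnitude and therefore exhibit
  correlated saliency across subjects;
* a left-hemisphere dominance expressed both as amplitude
  (``asymmetry_factor`` >= 1 boosts left-hemisphere effects) and as count
  (``affected_left_fraction`` of each block's cortical members are left);
* SRS-like subscores that are noisy linear functions of the latent effects,
  and totals banded strictly above / below the severity split;
* an unscored control group drawn from the low-severity end of the latent
  spectrum.

The latent model: each subject carries a severity budget ``t`` (uniform on
a group-specific interval, high > low > control) and shares it across the
``n_latents`` effect factors with centred allocation noise::

    z[s, l] = t[s] + latent_spread * (eps[s, l] - mean_l(eps[s, :]))

Centring makes the budget the only component common to different factors,
which keeps *cross*-block correlations weak (so threshold-filtered
correlation graphs can separate the blocks) while the shared budget still
separates the severity groups cleanly when pooled over factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import (
    NETWORKS,
    SUBSCORES,
    BrainVolume,
    CohortTruth,
    ParcellationAtlas,
    SizingError,
    SubjectRecord,
    ValidationError,
)

__all__ = ["CohortConfig", "generate_atlas", "generate_cohort", "truth_recovery_labels"]

LOBE_NAMES = ("frontal", "parietal", "temporal", "occipital", "insula", "limbic")

#: Severity-budget intervals per group.  Controls are drawn from the low
#: tail, overlapping the low-severity group from below.
BUDGET_RANGE = {"high": (1.5, 2.0), "low": (0.5, 1.0), "control": (0.3, 0.8)}


@dataclass
class CohortConfig:
    """Generator parameters; the defaults are the package's study conditions."""

    n_high: int = 60
    n_low: int = 60
    n_control: int = 30
    grid: int = 48
    n_cortical_per_hemi: int = 75
    n_subcortical_per_hemi: int = 13
    n_midline: int = 2
    n_lobes: int = 6
    n_networks: int = 8
    n_latents: int = 4
    effect_scale: float = 0.25
    noise_sd: float = 0.05
    subscore_noise_sd: float = 3.0
    seed: int = 0
    # secondary knobs (documented in the methods note)
    asymmetry_factor: float = 2.5
    latent_spread: float = 0.8
    affected_cortical_per_block: int = 10
    affected_subcortical_per_block: int = 2
    affected_left_fraction: float = 0.75
    texture_amplitude: float = 0.3

    def __post_init__(self) -> None:
        for name in ("n_high", "n_low", "n_control", "n_cortical_per_hemi", "n_lobes",
                     "n_networks", "n_latents"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.grid < 16:
            raise ValidationError("grid must be >= 16")
        if self.effect_scale < 0:
            raise ValidationError("effect_scale must be >= 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.asymmetry_factor < 1:
            raise ValidationError("asymmetry_factor must be >= 1 (left-dominant)")


# ---------------------------------------------------------------------------
# atlas

def _zones(grid: int):
    """Brain ellipsoid, cortical shell and subcortical core masks plus the
    normalised radius field."""
    c = (grid - 1) / 2.0
    r = np.array([0.44, 0.47, 0.44]) * grid
    idx = np.indices((grid, grid, grid)).astype(float)
    rho = np.sqrt(((idx[0] - c) / r[0]) ** 2
                  + ((idx[1] - c) / r[1]) ** 2
                  + ((idx[2] - c) / r[2]) ** 2)
    brain = rho <= 1.0
    core = rho <= 0.55
    shell = brain & ~core
    return brain, shell, core, rho


def _midline_masks(grid: int, n_midline: int, core: np.ndarray):
    """Up to two mirror-symmetric midline structures inside the core."""
    if n_midline == 0:
        return [], []
    if n_midline > 2:
        raise ValidationError("at most 2 midline structures are supported")
    c = (grid - 1) / 2.0
    x, y, z = np.indices((grid, grid, grid))
    near_mid = np.abs(x - c) <= 2.0
    masks, names = [], []
    # brain-stem analogue: central column, inferior half
    stem = near_mid & core & (np.abs(y - c) <= 0.14 * grid) & (z < c - 0.08 * grid)
    masks.append(stem)
    names.append("brainstem")
    if n_midline == 2:
        fx = near_mid & core & (np.abs(y - c) <= 0.10 * grid) \
            & (z >= c + 0.04 * grid) & (z <= c + 0.18 * grid)
        masks.append(fx & ~stem)
        names.append("fornix")
    return masks, names


def _voronoi_labels(mask: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Assign each voxel of ``mask`` to its nearest seed (1-based)."""
    vox = np.argwhere(mask).astype(float)
    d2 = ((vox[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    lab = np.zeros(mask.shape, dtype=np.int32)
    lab[mask] = d2.argmin(axis=1) + 1
    return lab


def _sample_seeds(rng, mask: np.ndarray, n: int) -> np.ndarray:
    vox = np.argwhere(mask)
    if len(vox) < n:
        raise SizingError(
            f"grid hosts only {len(vox)} candidate voxels for {n} regions"
        )
    # farthest-point style sampling for evenly spread, well-sized cells
    pick = [int(rng.integers(len(vox)))]
    d = ((vox - vox[pick[0]]) ** 2).sum(axis=1).astype(float)
    for _ in range(1, n):
        pick.append(int(d.argmax()))
        d = np.minimum(d, ((vox - vox[pick[-1]]) ** 2).sum(axis=1))
    return vox[pick].astype(float)


def generate_atlas(config: CohortConfig, rng: np.random.Generator | None = None) -> ParcellationAtlas:
    """Build a mirror-symmetric parcellation on the configured grid.

    Right-hemisphere regions are seeded on the low-index half of the
    sagittal axis; left-hemisphere regions are their mirror images, so the
    label volume reflected about the mid-sagittal plane maps each left
    region onto its right counterpart.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    G = config.grid
    c = (G - 1) / 2.0
    brain, shell, core, _ = _zones(G)

    mid_masks, mid_names = _midline_masks(G, config.n_midline, core)
    claimed = np.zeros((G, G, G), dtype=bool)
    for m in mid_masks:
        claimed |= m

    x = np.indices((G, G, G))[0]
    right = x < c  # low sagittal indices = right hemisphere

    n_c = config.n_cortical_per_hemi
    n_s = config.n_subcortical_per_hemi
    labels = np.zeros((G, G, G), dtype=np.int32)

    def place(zone_mask, n, id_offset):
        """Voronoi-fill the right half of a zone; mirror onto the left."""
        zr = zone_mask & right & ~claimed
        seeds = _sample_seeds(rng, zr, n)
        lab_r = _voronoi_labels(zr, seeds)
        lab_l = np.flip(lab_r, axis=0).copy()
        lab_l[lab_l > 0] += n
        block = lab_r + lab_l
        block[block > 0] += id_offset
        labels[block > 0] = block[block > 0]
        return seeds

    cort_seeds = place(shell, n_c, 0)
    if n_s > 0:
        place(core, n_s, 2 * n_c)
    next_id = 2 * n_c + 2 * n_s
    for i, m in enumerate(mid_masks):
        m = m & ~ (labels > 0)
        labels[m] = next_id + 1 + i

    # region table ---------------------------------------------------------
    rows = []
    # lobes: sort right cortical seeds by polar angle in the coronal-axial
    # plane and split into contiguous, near-equal sectors
    ang = np.arctan2(cort_seeds[:, 2] - c, cort_seeds[:, 1] - c)
    order = np.argsort(ang, kind="stable")
    lobe_of = {}
    chunks = np.array_split(order, config.n_lobes)
    lobe_names = [LOBE_NAMES[i] if i < len(LOBE_NAMES) else f"lobe{i + 1}"
                  for i in range(config.n_lobes)]
    for lobe_idx, chunk in enumerate(chunks):
        for si in chunk:
            lobe_of[int(si)] = lobe_names[lobe_idx]

    # functional networks: round-robin over a shuffled order of the right
    # cortical regions (mirrored to the left) so all 8 networks are covered
    nets = [NETWORKS[i % len(NETWORKS)] for i in range(n_c)]
    net_perm = rng.permutation(n_c)
    net_of = {int(net_perm[i]): nets[i] for i in range(n_c)}

    for hemi, offset in (("R", 0), ("L", n_c)):
        for i in range(n_c):
            rows.append({
                "region_id": offset + i + 1,
                "name": f"ctx-{hemi.lower()}h-{lobe_of[i]}-{i + 1}",
                "hemisphere": hemi,
                "lobe": lobe_of[i],
                "is_cortical": True,
                "network": net_of[i],
            })
    for hemi, offset in (("R", 2 * n_c), ("L", 2 * n_c + n_s)):
        for i in range(n_s):
            rows.append({
                "region_id": offset + i + 1,
                "name": f"sub-{hemi.lower()}h-{i + 1}",
                "hemisphere": hemi,
                "lobe": "subcortical",
                "is_cortical": False,
                "network": "none",
            })
    for i, name in enumerate(mid_names):
        rows.append({
            "region_id": next_id + 1 + i,
            "name": name,
            "hemisphere": "midline",
            "lobe": "subcortical",
            "is_cortical": False,
            "network": "none",
        })
    regions = pd.DataFrame(rows, columns=["region_id", "name", "hemisphere",
                                          "lobe", "is_cortical", "network"])

    # sizing check: every region needs >= 8 voxels
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    if len(ids) != len(regions):
        raise SizingError(
            f"grid {G} produced {len(ids)} non-empty regions for "
            f"{len(regions)} requested"
        )
    if counts.min() < 8:
        small = int(ids[counts.argmin()])
        raise SizingError(
            f"grid {G} too small: region {small} received {counts.min()} "
            f"voxels (< 8); reduce the region count or enlarge the grid"
        )
    return ParcellationAtlas(labels=labels, regions=regions)


# ---------------------------------------------------------------------------
# cohort

def _intensity_template(grid: int) -> np.ndarray:
    brain, shell, _, _ = _zones(grid)
    t = 0.25 + 0.75 * gaussian_filter(brain.astype(float), grid / 32.0)
    t += 0.15 * gaussian_filter(shell.astype(float), grid / 32.0)
    return t


def _pick_affected(rng, atlas: ParcellationAtlas, config: CohortConfig):
    """Disjoint region blocks, one per latent; left-weighted cortical picks."""
    blocks = []
    cort_L = list(atlas.ids_where(is_cortical=True, hemisphere="L"))
    cort_R = list(atlas.ids_where(is_cortical=True, hemisphere="R"))
    sub = list(atlas.ids_where(is_cortical=False))
    sub = [r for r in sub
           if atlas.regions.set_index("region_id").loc[r, "hemisphere"] != "midline"]
    rng.shuffle(cort_L), rng.shuffle(cort_R), rng.shuffle(sub)
    n_cort = config.affected_cortical_per_block
    n_sub = config.affected_subcortical_per_block
    nL = int(round(n_cort * config.affected_left_fraction))
    for _ in range(config.n_latents):
        take_L = min(nL, len(cort_L))
        take_R = min(n_cort - take_L, len(cort_R))
        take_S = min(n_sub, len(sub))
        block = [cort_L.pop() for _ in range(take_L)]
        block += [cort_R.pop() for _ in range(take_R)]
        block += [sub.pop() for _ in range(take_S)]
        if not block:
            raise SizingError("not enough regions to populate every latent block")
        blocks.append(sorted(block))
    return blocks


def generate_cohort(config: CohortConfig):
    """Generate (records, volumes, atlas, truth) for one synthetic cohort.

    Deterministic for a fixed config (including its seed).
    """
    ss = np.random.SeedSequence([config.seed, 202])
    r_atlas, r_truth, r_vol, r_score = [np.random.default_rng(s) for s in ss.spawn(4)]

    if config.effect_scale == 0:
        warnings.warn(
            "effect_scale is 0: severity groups are inseparable by construction",
            UserWarning,
            stacklevel=2,
        )

    atlas = generate_atlas(config, rng=r_atlas)
    G = config.grid
    L = config.n_latents

    blocks = _pick_affected(r_truth, atlas, config)
    affected = frozenset(r for b in blocks for r in b)
    region_ids = atlas.region_ids
    loadings = pd.DataFrame(0.0, index=region_ids, columns=range(L))
    hemi_of = atlas.region_attr("hemisphere")
    for l, block in enumerate(blocks):
        for r in block:
            loadings.loc[r, l] = r_truth.uniform(0.6, 1.0)

    # per-latent effect fields: loading * asymmetry * (1 + texture) * mask
    texture = gaussian_filter(r_truth.standard_normal((G, G, G)), G / 24.0)
    fields = np.zeros((L, G, G, G), dtype=np.float32)
    for l, block in enumerate(blocks):
        for r in block:
            m = atlas.labels == r
            tex = texture[m]
            sd = tex.std()
            tex = (tex - tex.mean()) / (sd if sd > 0 else 1.0)
            mod = np.clip(1.0 + config.texture_amplitude * tex, 0.2, None)
            asym = config.asymmetry_factor if hemi_of[r] == "L" else 1.0
            fields[l][m] = loadings.loc[r, l] * asym * mod

    # subjects --------------------------------------------------------------
    groups = (["high"] * config.n_high + ["low"] * config.n_low
              + ["control"] * config.n_control)
    n = len(groups)
    subject_ids = [f"sub-{i + 1:03d}" for i in range(n)]

    t = np.array([r_truth.uniform(*BUDGET_RANGE[g]) for g in groups])
    eps = r_truth.standard_normal((n, L))
    z = t[:, None] + config.latent_spread * (eps - eps.mean(axis=1, keepdims=True))
    subject_latents = pd.DataFrame(z, index=subject_ids, columns=range(L))

    template = _intensity_template(G).astype(np.float32)
    volumes = []
    for s in range(n):
        v = template + config.effect_scale * np.tensordot(
            z[s].astype(np.float32), fields, axes=1
        )
        v += config.noise_sd * r_vol.standard_normal((G, G, G)).astype(np.float32)
        volumes.append(BrainVolume(np.clip(v, 0.0, None)))

    # phenotypes ------------------------------------------------------------
    w = r_score.uniform(0.3, 1.0, size=(L, len(SUBSCORES)))
    w /= w.sum(axis=0, keepdims=True)
    subscore_weights = pd.DataFrame(w, index=range(L), columns=list(SUBSCORES))
    raw = z @ w  # (n, 5)

    records = []
    for s, (sid, g) in enumerate(zip(subject_ids, groups)):
        if g == "control":
            records.append(SubjectRecord(sid, g))
            continue
        subs = 30.0 + 25.0 * raw[s] \
            + config.subscore_noise_sd * r_score.standard_normal(len(SUBSCORES))
        subs = np.clip(subs, 0.0, 100.0)
        if g == "high":
            total = 70.0 + 28.0 * (t[s] - 1.5) / 0.5 + r_score.normal(0, 1.0)
            total = float(np.clip(total, 70.5, 100.0))
        else:
            total = 40.0 + 19.0 * (t[s] - 0.5) / 0.5 + r_score.normal(0, 1.0)
            total = float(np.clip(total, 20.0, 58.5))
        records.append(SubjectRecord(
            sid, g, srs_total=round(total, 1),
            subscores={k: round(float(v), 1) for k, v in zip(SUBSCORES, subs)},
        ))

    truth = CohortTruth(
        affected_regions=affected,
        loadings=loadings,
        subject_latents=subject_latents,
        subscore_weights=subscore_weights,
        asymmetry_factor=config.asymmetry_factor,
    )
    return records, volumes, atlas, truth


def truth_recovery_labels(truth: CohortTruth, atlas: ParcellationAtlas) -> np.ndarray:
    """Binary affected/unaffected vector over the atlas's region order."""
    ids = set(int(i) for i in atlas.region_ids)
    stray = set(truth.affected_regions) - ids
    if stray:
        raise ValidationError(
            f"truth names regions absent from the atlas: {sorted(stray)}"
        )
    return np.array([1 if int(r) in truth.affected_regions else 0
                     for r in atlas.region_ids], dtype=int)
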