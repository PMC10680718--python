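"""Synthetic cytokine panels, raw plates, and deposit images with ground truth.

The generators emulate the statistical structure of the study design the
analysis modules assume — two genotype-like groups sampled at one or more
culture timepoints, a ~30-analyte cytokine panel measured in technical
triplicate on a bead immunoassay, and fluorescence sections with diffuse
signal plus bright disc-shaped deposits — while recording every planted
effect and injected defect so downstream stages can be tested for recovery.

Concentrations follow a log-normal model (cytokine panels are nonnegative
and right-skewed); group effects are specified as standardized mean
differences on the log scale, so recovery expectations are distribution
free.  All draws come from named substreams of a single seed, so adding one
defect type does not shift the other draws, and identical specs + seed give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cleaning import PlateTable, drop_discordant_replicate

__all__ = [
    "PanelSpec",
    "PlateNoiseSpec",
    "ImageSpec",
    "PanelTruth",
    "PlateTruth",
    "ImageTruth",
    "simulate_panel",
    "simulate_plate",
    "simulate_image",
]

# fixed offsets per named substream, combined with the user seed
_STREAMS = {"baselines": 1, "signs": 2, "concentrations": 3,
            "replicates": 4, "outliers": 5, "beads": 6, "image": 7}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream]])


@dataclass(frozen=True)
class PanelSpec:
    """Design of a synthetic cytokine panel.

    ``n_per_group`` samples per group per timepoint; ``signature`` indexes
    the cytokines carrying a group effect of ``effect_size`` standardized
    (log-scale) units; ``trend`` gives one natural-scale multiplier per
    timepoint applied to the signature cytokines (a monotone decreasing
    trend emulates an age-dependent loss of secretion).  ``base_level`` is
    the log-scale grand mean (log pg/mL) and ``noise_sd`` the log-scale
    biological noise.  Concentrations below ``censor_limit`` are reported
    as 0 in the clean-shaped output.
    """

    n_per_group: int = 5
    p: int = 30
    signature: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    effect_size: float = 2.0
    trend: tuple[float, ...] = (1.0,)
    timepoints: tuple[float, ...] | None = None
    group_names: tuple[str, str] = ("control", "AD")
    base_level: float = 4.0
    noise_sd: float = 0.5
    censor_limit: float = 3.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if any(j < 0 or j >= self.p for j in self.signature):
            raise ValueError("signature index out of range")
        if self.timepoints is not None and len(self.timepoints) != len(self.trend):
            raise ValueError("timepoints must match trend length")


@dataclass(frozen=True)
class PanelTruth:
    """Ground truth behind a simulated panel."""

    signature: tuple[int, ...]
    signs: np.ndarray  # +1 cytokine up in group_names[1], -1 down
    true_means: pd.DataFrame  # per-sample expected concentration, pg/mL
    uncensored: pd.DataFrame  # drawn concentrations before censoring


@dataclass(frozen=True)
class PlateNoiseSpec:
    """Technical noise and injected defects for a raw triplicate plate."""

    replicate_cv: float = 0.05
    outlier_prob: float = 0.0
    outlier_scale: float = 10.0
    low_bead_prob: float = 0.0
    bead_mean: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("outlier_prob", "low_bead_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.replicate_cv > 0:
            raise ValueError("replicate_cv must be > 0")


@dataclass(frozen=True)
class PlateTruth:
    """Injected defect locations: (sample_id, analyte, replicate) triples."""

    outliers: list[tuple[str, str, int]] = field(default_factory=list)
    low_bead_wells: list[tuple[str, str, int]] = field(default_factory=list)


@dataclass(frozen=True)
class ImageSpec:
    """Geometry of a synthetic fluorescence section.

    A central disc-shaped "organoid" occupies ``1 - background_fraction`` of
    the grid; pixels outside it are background (0).  Foreground pixels carry
    diffuse signal clipped to (0, threshold] so diffuse staining alone never
    classifies TRUE, plus ``n_deposits`` disc-shaped deposits of radius
    ``deposit_radius`` at constant ``deposit_intensity`` (> threshold).
    """

    H: int = 64
    W: int = 64
    background_fraction: float = 0.3
    diffuse_mean: float = 30.0
    diffuse_sd: float = 8.0
    n_deposits: int = 3
    deposit_radius: int = 4
    deposit_intensity: int = 120
    threshold: float = 73.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.H < 8 or self.W < 8:
            raise ValueError("image dimensions must be >= 8")
        if not self.deposit_intensity > self.diffuse_mean:
            raise ValueError("deposit_intensity must exceed diffuse_mean")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must be in [0, 1)")


@dataclass(frozen=True)
class ImageTruth:
    """Planted deposit geometry and the resulting expected statistic."""

    deposit_mask: np.ndarray
    organoid_mask: np.ndarray
    true_percent_true: float
    deposit_centers: list[tuple[int, int]]


def simulate_panel(spec: PanelSpec) -> tuple[pd.DataFrame, pd.Series, PanelTruth]:
    """Draw a clean-shaped samples x cytokines panel with known truth.

    Returns ``(matrix, meta, truth)``: the censored concentration matrix
    (pg/mL), a per-sample metadata frame with ``group`` and ``timepoint``
    columns, and the ground truth.
    """
    n_t = len(spec.trend)
    timepoints = (
        tuple(spec.timepoints) if spec.timepoints is not None
        else tuple(range(2, 2 + n_t))
    )
    baselines = spec.base_level + _rng(spec.seed, "baselines").normal(0, 1.0, spec.p)
    signs = np.zeros(spec.p)
    sig = list(spec.signature)
    signs[sig] = np.where(_rng(spec.seed, "signs").random(len(sig)) < 0.5, -1.0, 1.0)

    rows, sample_ids, groups, tps = [], [], [], []
    crng = _rng(spec.seed, "concentrations")
    for ti, tp in enumerate(timepoints):
        for gi, g in enumerate(spec.group_names):
            for r in range(spec.n_per_group):
                mu = baselines.copy()
                # group effect on signature cytokines, standardized log scale
                mu[sig] += (gi - 0.5) * signs[sig] * spec.effect_size * spec.noise_sd
                # timepoint multiplier on signature cytokines, natural scale
                mu[sig] += np.log(spec.trend[ti])
                rows.append(mu)
                sample_ids.append(f"{g}_t{tp}_s{r + 1}")
                groups.append(g)
                tps.append(tp)
    mu_mat = np.array(rows)
    logc = mu_mat + crng.normal(0, spec.noise_sd, mu_mat.shape)
    conc = np.exp(logc)

    analytes = [f"CK{j + 1:02d}" for j in range(spec.p)]
    uncensored = pd.DataFrame(conc, index=sample_ids, columns=analytes)
    censored = uncensored.where(uncensored >= spec.censor_limit, 0.0)
    meta = pd.DataFrame(
        {"group": groups, "timepoint": tps}, index=pd.Index(sample_ids, name="sample_id")
    )
    truth = PanelTruth(
        signature=tuple(sig),
        signs=signs,
        true_means=pd.DataFrame(np.exp(mu_mat), index=sample_ids, columns=analytes),
        uncensored=uncensored,
    )
    return censored, meta, truth


def _concordant_triplet(base, rng, sigma, detection_limit, max_draws=200):
    """Draw a triplicate that the discordance rule retains in full.

    Ordinary (non-defect) wells are modeled as concordant: a triplet whose
    censored values would trip the 2x-distance rule is redrawn, so every
    discordance removal downstream traces back to an injected defect and the
    cleaning report is fully determined by the recorded truth.
    """
    for _ in range(max_draws):
        reps = base * np.exp(rng.normal(0, sigma, 3))
        cens = np.where(reps < detection_limit, 0.0, reps)
        _, removed = drop_discordant_replicate(cens)
        if removed is None:
            return reps
    raise RuntimeError("could not draw a concordant triplet")


def simulate_plate(
    uncensored: pd.DataFrame,
    meta: pd.DataFrame,
    noise: PlateNoiseSpec,
    *,
    min_beads: int = 35,
    detection_limit: float = 3.2,
) -> tuple[PlateTable, PlateTruth]:
    """Expand per-sample concentrations into a raw triplicate plate.

    Each cell's three replicates multiply the sample concentration by
    log-normal noise of coefficient of variation ``replicate_cv``,
    constrained to concordance (see :func:`_concordant_triplet`).  With
    probability ``outlier_prob`` per cell, one replicate is made discordant
    (multiplied or divided by ``outlier_scale``); with probability
    ``low_bead_prob`` per reading the bead count is drawn below
    ``min_beads``.  Both defect locations are recorded in the truth.
    """
    rrng = _rng(noise.seed, "replicates")
    orng = _rng(noise.seed, "outliers")
    brng = _rng(noise.seed, "beads")
    truth = PlateTruth()
    sigma = noise.replicate_cv  # log-normal sigma ~ CV for small CV
    records = []
    for sid in uncensored.index:
        g = str(meta.loc[sid, "group"])
        for analyte in uncensored.columns:
            base = float(uncensored.loc[sid, analyte])
            reps = _concordant_triplet(base, rrng, sigma, detection_limit)
            if orng.random() < noise.outlier_prob:
                k = int(orng.integers(3))
                factor = noise.outlier_scale if orng.random() < 0.5 else 1.0 / noise.outlier_scale
                reps[k] *= factor
                truth.outliers.append((str(sid), str(analyte), k + 1))
            for k in range(3):
                if brng.random() < noise.low_bead_prob:
                    beads = int(brng.integers(5, min_beads))
                    truth.low_bead_wells.append((str(sid), str(analyte), k + 1))
                else:
                    beads = max(int(brng.poisson(noise.bead_mean)), min_beads)
                records.append(
                    {
                        "sample_id": sid,
                        "group": g,
                        "analyte": analyte,
                        "replicate": k + 1,
                        "concentration": float(reps[k]),
                        "bead_count": beads,
                    }
                )
    plate = PlateTable(pd.DataFrame.from_records(records), min_beads=min_beads)
    return plate, truth


def simulate_image(spec: ImageSpec) -> tuple[np.ndarray, ImageTruth]:
    """Render a synthetic section and compute its expected deposit statistic.

    Deposits are placed uniformly at random wholly inside the organoid disc
    (overlap allowed); raises if a deposit cannot fit.  The expected
    percent-TRUE is derived from the planted geometry alone: diffuse pixels
    are clipped to at most the threshold, so a pixel classifies TRUE exactly
    when it and all of its existing neighbors are deposit pixels — a literal
    per-pixel erosion of the deposit mask, evaluated here independently of
    the classifier module.
    """
    rng = _rng(spec.seed, "image")
    H, W = spec.H, spec.W
    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2, (W - 1) / 2
    r_org = np.sqrt((1 - spec.background_fraction) * H * W / np.pi)
    organoid = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_org**2

    diffuse = rng.normal(spec.diffuse_mean, spec.diffuse_sd, (H, W))
    diffuse = np.clip(np.rint(diffuse), 1, int(spec.threshold))
    image = np.where(organoid, diffuse, 0).astype(np.int64)

    if spec.deposit_radius >= r_org:
        raise ValueError("deposit radius exceeds the organoid region")
    deposit_mask = np.zeros((H, W), dtype=bool)
    centers: list[tuple[int, int]] = []
    for _ in range(spec.n_deposits):
        for _attempt in range(1000):
            dy = int(rng.integers(0, H))
            dx = int(rng.integers(0, W))
            disc = (yy - dy) ** 2 + (xx - dx) ** 2 <= spec.deposit_radius**2
            if disc.sum() and np.all(organoid[disc]):
                deposit_mask |= disc
                centers.append((dy, dx))
                break
        else:
            raise ValueError("could not place a deposit inside the organoid")
    image[deposit_mask] = spec.deposit_intensity

    # expected TRUE set from geometry: pixel and every existing neighbor
    # must lie in the deposit mask (deposit intensity is the only value
    # strictly above the threshold by construction)
    n_true = 0
    for i in range(H):
        for j in range(W):
            if not deposit_mask[i, j]:
                continue
            ok = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < H and 0 <= jj < W and not deposit_mask[ii, jj]:
                        ok = False
            n_true += ok
    n_fg = int(organoid.sum())
    truth = ImageTruth(
        deposit_mask=deposit_mask,
        organoid_mask=organoid,
        true_percent_true=100.0 * n_true / n_fg,
        deposit_centers=centers,
    )
    return image, truth
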