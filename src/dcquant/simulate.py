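"""Synthetic microscopy stacks, RNA-seq count matrices, and viability tables.

Every generator returns its ground truth alongside the data, so each
downstream quantification can be tested for parameter recovery without any
external data.  All generators are bit-reproducible given (params, seed).

The image generator emulates a dissected intestinal nucleus: a large solid
ellipsoid (intestinal cells are 32-ploid, hence ~10 um nuclei) rendered in
physical micrometer coordinates onto an anisotropic voxel grid, containing a
chromosome territory occupying a controllable fraction of the nuclear volume
at a controllable radial position, with a controllable stain enrichment.
The count generator emulates a two-condition mRNA-seq design with negative
binomial replicate noise and a uniform multiplicative shift 2^d applied to
X-linked genes in the treatment group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .stacks import BinaryMask2D, BinaryMask3D, VoxelStack
from .viability import ViabilityRecord
from .zones import fit_ellipse, make_zones, zone_fractions

# ---------------------------------------------------------------------------
# image stacks

@dataclass
class ImageSimParams:
    """Geometry, photometry, and noise of one synthetic nucleus.

    ``f_true`` is the territory volume fraction, ``r_true`` its radial
    position in the mid-plane (0 = nuclear centroid, 1 = touching the
    boundary along a seeded random direction), ``k_true`` the territory mean
    intensity over the non-territory nuclear mean in the signal channel.
    """

    shape: tuple[int, int, int] = (32, 128, 128)  # (nz, ny, nx)
    spacing: tuple[float, float, float] = (0.2, 0.1, 0.1)  # um
    semiaxes_um: tuple[float, float, float] = (2.4, 5.0, 4.5)  # (z, y, x)
    f_true: float = 0.125
    r_true: float = 0.5
    k_true: float = 4.0
    nuclear_base: float = 100.0
    background_level: float = 10.0
    gradient_amplitude: float = 0.0
    noise_scale: float = 2.0
    photons_per_unit: float = 4.0
    irregular: bool = False
    irregular_amp: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        nz, ny, nx = self.shape
        if nz < 10:
            raise ValueError("nz must be >= 10 (stacks are trimmed to >= 10 nuclear planes)")
        if not (0.0 < self.f_true <= 1.0):
            raise ValueError("f_true must be in (0, 1]")
        if not (0.0 <= self.r_true <= 1.0):
            raise ValueError("r_true must be in [0, 1]")
        if self.k_true < 1.0:
            raise ValueError("k_true must be >= 1")
        if self.nuclear_base <= 0 or self.background_level < 0:
            raise ValueError("intensities must be positive")
        if self.photons_per_unit <= 0:
            raise ValueError("photons_per_unit must be positive")
        dz, dy, dx = self.spacing
        az, ay, ax = self.semiaxes_um
        if az > (nz - 1) / 2 * dz or ay > (ny - 1) / 2 * dy or ax > (nx - 1) / 2 * dx:
            raise ValueError("nucleus semi-axes do not fit inside the grid")


@dataclass
class ImageTruth:
    """Noise-free ground truth accompanying one synthetic stack."""

    nucleus_mask: BinaryMask3D
    territory_mask: BinaryMask3D
    realized_fraction: float
    zone_fractions_mid: tuple[float, float, float] | None
    mid_slice: int
    k_true: float
    seed: int


#: Fig-style calibration presets: compact wild-type-like territories occupy
#: about an eighth of the nuclear volume; decondensed territories about a fifth.
WT_LIKE = ImageSimParams(f_true=0.125)
DECONDENSED_LIKE = ImageSimParams(f_true=0.20)
PRESETS = {"wt-like": WT_LIKE, "decondensed-like": DECONDENSED_LIKE}


def preset(name: str, **overrides) -> ImageSimParams:
    """Return a named calibration preset, optionally with field overrides."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(base, **overrides)


def _normalized_coords(params: ImageSimParams) -> tuple[np.ndarray, ...]:
    """Voxel-center coordinates divided by the nucleus semi-axes (unit ball = nucleus)."""
    nz, ny, nx = params.shape
    dz, dy, dx = params.spacing
    az, ay, ax = params.semiaxes_um
    cz, cy, cx = (nz - 1) / 2 * dz, (ny - 1) / 2 * dy, (nx - 1) / 2 * dx
    z = (np.arange(nz) * dz - cz) / az
    y = (np.arange(ny) * dy - cy) / ay
    x = (np.arange(nx) * dx - cx) / ax
    return np.meshgrid(z, y, x, indexing="ij")


def generate_nucleus_stack(params: ImageSimParams) -> tuple[VoxelStack, VoxelStack, ImageTruth]:
    """Render one nucleus; returns (nuclear-stain stack, signal stack, truth).

    The territory is the ``f_true``-quantile sublevel set, over nuclear
    voxels, of the distance (in nucleus-normalized coordinates) from a centre
    offset by ``r_true`` of the maximal in-plane offset — an ellipsoidal blob
    similar to the nucleus whose realized voxel fraction matches ``f_true``
    to within one voxel.  In irregular mode the distance is modulated by a
    smoothed noise field, perturbing the blob boundary.
    """
    rng = np.random.default_rng(params.seed)
    qz, qy, qx = _normalized_coords(params)
    nucleus = qz**2 + qy**2 + qx**2 <= 1.0
    n_nuc = int(nucleus.sum())
    if n_nuc == 0:
        raise ValueError("nucleus rendered no voxels; enlarge the semi-axes")

    s = params.f_true ** (1.0 / 3.0)
    max_offset = 1.0 - s
    if params.r_true * max_offset > 1.0:
        raise ValueError(
            f"territory with f_true={params.f_true} cannot sit at r_true={params.r_true}"
        )
    phi = rng.uniform(0.0, 2.0 * np.pi)  # seeded random mid-plane direction
    off = params.r_true * max_offset
    c_norm = np.array([0.0, off * np.sin(phi), off * np.cos(phi)])

    dist = np.sqrt((qz - c_norm[0]) ** 2 + (qy - c_norm[1]) ** 2 + (qx - c_norm[2]) ** 2)
    if params.irregular and params.irregular_amp > 0:
        noise = ndi.gaussian_filter(rng.standard_normal(params.shape), sigma=4.0)
        noise /= max(np.abs(noise).max(), 1e-12)
        dist = dist / (1.0 + params.irregular_amp * noise)

    n_terr = int(round(params.f_true * n_nuc))
    territory = np.zeros(params.shape, dtype=bool)
    if n_terr >= n_nuc:
        territory = nucleus.copy()
    elif n_terr > 0:
        vals = dist[nucleus]
        thresh = np.partition(vals, n_terr - 1)[n_terr - 1]
        territory = nucleus & (dist <= thresh)
        # resolve threshold ties deterministically toward the exact count
        excess = int(territory.sum()) - n_terr
        if excess > 0:
            tie = np.argwhere(territory & (dist == thresh))
            for iz, iy, ix in tie[:excess]:
                territory[iz, iy, ix] = False
    realized = float(territory.sum()) / n_nuc

    dapi = np.where(nucleus, params.nuclear_base, params.background_level).astype(float)
    sig = np.where(nucleus, params.nuclear_base, params.background_level).astype(float)
    sig[territory] = params.k_true * params.nuclear_base

    if params.gradient_amplitude:
        ramp = params.gradient_amplitude * (np.arange(params.shape[2]) / max(params.shape[2] - 1, 1))
        dapi = dapi + ramp[None, None, :]
        sig = sig + ramp[None, None, :]
    if params.noise_scale > 0:
        # Poisson-Gaussian camera model: shot noise in photon units (gain
        # photons_per_unit per intensity count) plus Gaussian read noise of
        # sd noise_scale intensity counts.
        g = params.photons_per_unit
        dapi = rng.poisson(dapi * g) / g + rng.normal(0.0, params.noise_scale, size=dapi.shape)
        sig = rng.poisson(sig * g) / g + rng.normal(0.0, params.noise_scale, size=sig.shape)
        dapi = np.clip(dapi, 0.0, None)
        sig = np.clip(sig, 0.0, None)

    # mid-plane of the symmetric ellipsoid: voxel plane nearest the nuclear centre
    mid = int(round((params.shape[0] - 1) / 2))
    zf = None
    nuc_slice = BinaryMask2D(nucleus[mid], provenance="nucleus")
    terr_slice = BinaryMask2D(territory[mid], provenance="signal")
    if nuc_slice.count() >= 3 and terr_slice.count() > 0:
        ell = fit_ellipse(nuc_slice)
        zs = make_zones(ell, nuc_slice.shape)
        try:
            zf = zone_fractions(terr_slice, zs)
        except ValueError:
            zf = None

    truth = ImageTruth(
        nucleus_mask=BinaryMask3D(nucleus, provenance="nucleus"),
        territory_mask=BinaryMask3D(territory, provenance="signal"),
        realized_fraction=realized,
        zone_fractions_mid=zf,
        mid_slice=mid,
        k_true=params.k_true,
        seed=params.seed,
    )
    return (
        VoxelStack(dapi, spacing=params.spacing, channel="dapi"),
        VoxelStack(sig, spacing=params.spacing, channel="sig"),
        truth,
    )


# ---------------------------------------------------------------------------
# count matrices

#: Chromosome vocabulary and WBcel235 lengths (bp), used for coordinates.
CHROM_LENGTHS = {
    "I": 15_072_434,
    "II": 15_279_421,
    "III": 13_783_801,
    "IV": 17_493_829,
    "V": 20_924_180,
    "X": 17_718_942,
}

_DEFAULT_GENES = {"I": 3440, "II": 3440, "III": 3440, "IV": 3440, "V": 3440, "X": 2800}


@dataclass
class CountSimParams:
    """Negative-binomial mRNA-seq design with a uniform X shift.

    ``d_true`` (log2 units) multiplies treatment-group means of X-linked
    genes by ``2**d_true`` and plays the role of the X-derepression statistic
    the downstream estimator recovers.  Defaults mirror a ~20,000-gene
    genome with ~14% X-linked genes and three replicates per condition.
    """

    genes_per_chrom: dict = field(default_factory=lambda: dict(_DEFAULT_GENES))
    mean_log: float = float(np.log(150.0))
    sigma_log: float = 1.0
    dispersion: float = 0.05
    n_control: int = 3
    n_treatment: int = 3
    d_true: float = 0.0
    lib_factor_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_control, (int, np.integer)) or not isinstance(
            self.n_treatment, (int, np.integer)
        ):
            raise ValueError("replicate counts must be integers")
        if self.n_control < 2 or self.n_treatment < 2:
            raise ValueError("need >= 2 samples per group")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not np.isfinite(self.d_true):
            raise ValueError("d_true must be finite")
        unknown = set(self.genes_per_chrom) - set(CHROM_LENGTHS)
        if unknown:
            raise ValueError(f"unknown chromosomes {sorted(unknown)}")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws parameterized by mean and dispersion alpha (var = mu + alpha mu^2)."""
    if dispersion == 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def generate_count_matrix(
    params: CountSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate counts; returns (counts, gene table, truth record).

    Counts are genes x samples with columns ``ctrl_1.. trt_1..``; the gene
    table carries ``gene_id, chrom, start`` (1-based).  Control means are
    drawn once from a log-normal; treatment means equal control means except
    X-linked genes are multiplied by ``2**d_true``; NB noise is applied and
    each sample is scaled by its library-size factor.
    """
    rng = np.random.default_rng(params.seed)
    chroms = np.concatenate(
        [np.repeat(c, n) for c, n in params.genes_per_chrom.items() if n > 0]
    )
    n_genes = chroms.size
    gene_ids = np.array([f"gene{i + 1:05d}" for i in range(n_genes)])
    starts = np.array(
        [rng.integers(1, CHROM_LENGTHS[c] + 1) for c in chroms], dtype=np.int64
    )

    base_mean = rng.lognormal(params.mean_log, params.sigma_log, size=n_genes)
    on_x = chroms == "X"
    trt_mean = np.where(on_x, base_mean * 2.0**params.d_true, base_mean)

    lo, hi = params.lib_factor_range
    n_samp = params.n_control + params.n_treatment
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samp))

    cols, data = [], []
    for j in range(params.n_control):
        cols.append(f"ctrl_{j + 1}")
        data.append(_nb_sample(rng, base_mean * lib[j], params.dispersion))
    for j in range(params.n_treatment):
        cols.append(f"trt_{j + 1}")
        data.append(_nb_sample(rng, trt_mean * lib[params.n_control + j], params.dispersion))

    counts = pd.DataFrame(np.column_stack(data), index=gene_ids, columns=cols)
    counts.index.name = "gene_id"
    genes = pd.DataFrame({"gene_id": gene_ids, "chrom": chroms, "start": starts})
    truth = {
        "d_true": params.d_true,
        "base_mean": base_mean,
        "treatment_mean": trt_mean,
        "library_factors": dict(zip(cols, lib)),
        "groups": {c: ("control" if c.startswith("ctrl") else "treatment") for c in cols},
        "seed": params.seed,
    }
    return counts, genes, truth


# ---------------------------------------------------------------------------
# viability tables

@dataclass
class ViabilitySimParams:
    """Two-stage binomial survival model for one genotype's brood."""

    n_embryos: int = 600
    p_embryonic_death: float = 0.1
    p_larval_death: float = 0.05
    genotype: str = "sim"
    condition: str = "no-auxin"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_embryos < 0:
            raise ValueError("embryo count must be non-negative")
        for p in (self.p_embryonic_death, self.p_larval_death):
            if not (0.0 <= p <= 1.0):
                raise ValueError("death probabilities must be in [0, 1]")


def generate_viability_table(params: ViabilitySimParams) -> ViabilityRecord:
    """Binomial draws per stage; laid = dead embryos + dead larvae + adults."""
    rng = np.random.default_rng(params.seed)
    dead_embryo = int(rng.binomial(params.n_embryos, params.p_embryonic_death))
    hatched = params.n_embryos - dead_embryo
    dead_larva = int(rng.binomial(hatched, params.p_larval_death))
    return ViabilityRecord(
        genotype=params.genotype,
        condition=params.condition,
        laid=params.n_embryos,
        dead_embryo=dead_embryo,
        dead_larva=dead_larva,
        adult=hatched - dead_larva,
    )
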