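"""Seeded synthetic-data generators with known ground truth for every
pipeline stage.

The phantom generator emulates fixed-cell confocal acquisition of U2OS-like
nuclei: axis-aligned ellipsoidal nuclei on a 47 x 47 x 200 nm voxel grid,
DNA-counterstain in channel 0, and DNA-damage foci rendered as Gaussian
blobs that are isotropic in micrometres (hence anisotropic in voxels) in the
γH2AX and SMC6 channels.  Each γH2AX focus carries a co-centered SMC6 focus
with probability ``coloc_prob``; additional SMC6-only foci are optional.
Noise is Poisson shot noise plus additive Gaussian read noise.

Further generators produce clonogenic colony-count tables under a
linear-quadratic survival law, DNA-content samples from a G0/1-S-G2/M
mixture (with an optional colcemid-arrested residual subpopulation),
lognormal division-interval tracks, and a synthetic edited-locus template
for the Surveyor arithmetic.

All generators are deterministic for a fixed seed; ``seed`` accepts anything
``numpy.random.default_rng`` does (int, SeedSequence, Generator).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import crispr
from .cellcycle import DivisionTracks, DNAContentSample
from .imaging import DEFAULT_VOXEL_SIZE_NM, ImageStack

CHANNELS = ("DNA", "gH2AX", "SMC6")


class GeometryError(ValueError):
    """Requested phantom geometry does not fit the stack."""


@dataclass
class FociPhantomParams:
    """Parameters of the 3-channel foci phantom.

    Counts may be fixed integers or a ``("poisson", mean)`` spec.  ``snr``
    is the (γH2AX, SMC6) signal-to-background ratio pair: the peak blob
    amplitude is ``snr * sqrt(bg + read_noise_sd**2)``, i.e. the peak stands
    ``snr`` background-noise standard deviations above the intranuclear
    background.  Defaults mirror the acquisition SNR settings of 10 (red,
    γH2AX) and 12 (green, SMC6).
    """

    stack_shape: tuple[int, int, int] = (42, 336, 448)  # (z, y, x) voxels
    voxel_size_nm: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_NM
    n_nuclei: int = 10
    nucleus_radii_um: tuple[float, float, float] = (1.4, 2.4, 2.4)
    n_gh2ax_per_nucleus: int | tuple = 8
    coloc_prob: float = 0.5
    extra_smc6: int | tuple = 2
    focus_sigma_um: float = 0.2
    snr: tuple[float, float] = (10.0, 12.0)
    noise: bool = True
    read_noise_sd: float = 2.0
    dna_levels: tuple[float, float] = (10.0, 100.0)  # (outside, inside nucleus)
    focus_bg: tuple[float, float] = (5.0, 20.0)  # (outside, inside nucleus)
    min_sep_um: float = 0.9
    seed: int | object = 0

    def validate(self) -> None:
        if not 0.0 <= self.coloc_prob <= 1.0:
            raise ValueError("coloc_prob must be in [0, 1]")
        if len(self.stack_shape) != 3 or any(s < 1 for s in self.stack_shape):
            raise ValueError("stack_shape must be a positive (z,y,x) triple")
        if any(v <= 0 for v in self.voxel_size_nm):
            raise ValueError("voxel sizes must be positive")
        if any(r <= 0 for r in self.nucleus_radii_um):
            raise ValueError("nucleus radii must be positive")
        if self.focus_sigma_um <= 0 or self.min_sep_um <= 0:
            raise ValueError("focus_sigma_um and min_sep_um must be positive")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")


@dataclass
class NucleusTruth:
    """Ground truth for a single nucleus (coordinates in µm, stack frame)."""

    label: int
    center_um: np.ndarray
    radii_um: np.ndarray
    gh2ax_centers_um: np.ndarray  # (n, 3)
    coloc_flags: np.ndarray  # (n,) bool
    smc6_only_centers_um: np.ndarray  # (m, 3)

    @property
    def n_gh2ax(self) -> int:
        return len(self.gh2ax_centers_um)

    @property
    def n_smc6(self) -> int:
        return int(self.coloc_flags.sum()) + len(self.smc6_only_centers_um)

    @property
    def n_overlap(self) -> int:
        return int(self.coloc_flags.sum())

    def contains_um(self, point_um) -> bool:
        d = (np.asarray(point_um) - self.center_um) / self.radii_um
        return bool((d**2).sum() <= 1.0)


@dataclass
class GroundTruth:
    nuclei: list[NucleusTruth] = field(default_factory=list)

    def __post_init__(self) -> None:
        for nt in self.nuclei:
            if nt.n_overlap > min(nt.n_gh2ax, nt.n_smc6):
                raise ValueError("n_overlap exceeds min(n_gh2ax, n_smc6)")

    @property
    def total_gh2ax(self) -> int:
        return sum(n.n_gh2ax for n in self.nuclei)

    @property
    def total_smc6(self) -> int:
        return sum(n.n_smc6 for n in self.nuclei)

    @property
    def total_overlap(self) -> int:
        return sum(n.n_overlap for n in self.nuclei)

    def nucleus_at_um(self, point_um) -> NucleusTruth | None:
        for nt in self.nuclei:
            if nt.contains_um(point_um):
                return nt
        return None

    def to_json(self, path) -> None:
        payload = [
            {
                "label": nt.label,
                "center_um": nt.center_um.tolist(),
                "radii_um": nt.radii_um.tolist(),
                "gh2ax_centers_um": nt.gh2ax_centers_um.tolist(),
                "coloc_flags": nt.coloc_flags.astype(int).tolist(),
                "smc6_only_centers_um": nt.smc6_only_centers_um.tolist(),
            }
            for nt in self.nuclei
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        nuclei = [
            NucleusTruth(
                label=d["label"],
                center_um=np.asarray(d["center_um"], float),
                radii_um=np.asarray(d["radii_um"], float),
                gh2ax_centers_um=np.asarray(d["gh2ax_centers_um"], float).reshape(-1, 3),
                coloc_flags=np.asarray(d["coloc_flags"], bool),
                smc6_only_centers_um=np.asarray(
                    d["smc6_only_centers_um"], float
                ).reshape(-1, 3),
            )
            for d in payload
        ]
        return cls(nuclei)


def _draw_count(rng: np.random.Generator, spec) -> int:
    if isinstance(spec, (int, np.integer)):
        return int(spec)
    kind, mean = spec
    if kind != "poisson":
        raise ValueError(f"unknown count distribution {kind!r}")
    return int(rng.poisson(mean))


def _nucleus_centers(
    rng: np.random.Generator, params: FociPhantomParams
) -> list[np.ndarray]:
    """Row-major tiled placement with jitter; centers in voxel units (z,y,x)."""
    nz, ny, nx = params.stack_shape
    dz, dy, dx = (v / 1000.0 for v in params.voxel_size_nm)
    rz = params.nucleus_radii_um[0] / dz
    ry = params.nucleus_radii_um[1] / dy
    rx = params.nucleus_radii_um[2] / dx
    margin = 4  # voxels kept clear of tile and XY image borders
    min_ty = int(math.ceil(2 * ry)) + 2 * margin
    min_tx = int(math.ceil(2 * rx)) + 2 * margin
    tiles_y, tiles_x = ny // min_ty, nx // min_tx
    if nz < int(math.ceil(2 * rz)) + 4 or tiles_y * tiles_x < params.n_nuclei:
        raise GeometryError(
            f"stack {params.stack_shape} too small for {params.n_nuclei} nuclei "
            f"of radii {params.nucleus_radii_um} µm"
        )
    ty, tx = ny / tiles_y, nx / tiles_x
    centers = []
    for k in range(params.n_nuclei):
        iy, ix = divmod(k, tiles_x)
        cy0 = (iy + 0.5) * ty
        cx0 = (ix + 0.5) * tx
        jy = max(ty / 2 - ry - margin, 0.0)
        jx = max(tx / 2 - rx - margin, 0.0)
        cy = cy0 + rng.uniform(-jy, jy)
        cx = cx0 + rng.uniform(-jx, jx)
        cz = rng.uniform(rz + 2, nz - rz - 2)
        centers.append(np.array([cz, cy, cx]))
    return centers


def _place_points_in_ellipsoid(
    rng: np.random.Generator,
    n: int,
    radii_um: np.ndarray,
    min_sep_um: float,
    shrink: float = 0.75,
) -> np.ndarray:
    """Centers (µm, nucleus frame) inside the shrunk ellipsoid with a minimum
    pairwise separation.  The separation is relaxed geometrically if random
    sequential placement stalls, down to a floor of 0.55 µm."""
    pts: list[np.ndarray] = []
    sep = float(min_sep_um)
    attempts = 0
    while len(pts) < n:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = rng.random() ** (1.0 / 3.0)
        cand = u * r * shrink * radii_um
        if all(np.linalg.norm(cand - p) >= sep for p in pts):
            pts.append(cand)
            attempts = 0
            continue
        attempts += 1
        if attempts > 500:
            if sep <= 0.55:
                raise GeometryError(
                    f"cannot place {n} foci with separation >= {sep:.2f} µm "
                    f"in nucleus of radii {radii_um} µm"
                )
            sep = max(sep * 0.85, 0.55)
            attempts = 0
    return np.array(pts).reshape(n, 3)


def _add_ellipsoid(img, center_vox, radii_um, voxel_um, amplitude) -> None:
    c = np.asarray(center_vox, float)
    r_vox = np.asarray(radii_um) / np.asarray(voxel_um)
    lo = np.maximum(np.floor(c - r_vox).astype(int) - 1, 0)
    hi = np.minimum(np.ceil(c + r_vox).astype(int) + 2, img.shape)
    grids = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    q = sum(((g - cc) / rr) ** 2 for g, cc, rr in zip(grids, c, r_vox))
    region = tuple(slice(l, h) for l, h in zip(lo, hi))
    img[region][q <= 1.0] += amplitude


def _add_blob(img, center_um, sigma_um, voxel_um, amplitude) -> None:
    c_vox = np.asarray(center_um) / np.asarray(voxel_um)
    r_vox = 4.0 * sigma_um / np.asarray(voxel_um)
    lo = np.maximum(np.floor(c_vox - r_vox).astype(int), 0)
    hi = np.minimum(np.ceil(c_vox + r_vox).astype(int) + 1, img.shape)
    if np.any(lo >= hi):
        return
    grids = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    d2 = sum(
        ((g * v - cu) ** 2) for g, v, cu in zip(grids, voxel_um, center_um)
    )
    region = tuple(slice(l, h) for l, h in zip(lo, hi))
    img[region] += amplitude * np.exp(-d2 / (2.0 * sigma_um**2))


def gen_foci_stack(params: FociPhantomParams) -> tuple[ImageStack, GroundTruth]:
    """Render a 3-channel phantom (DNA, γH2AX, SMC6) with ground truth.

    Every focus center lies strictly inside its nucleus ellipsoid; each
    γH2AX focus is SMC6-co-centered with probability ``coloc_prob``.
    Identical parameters and seed give bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    voxel_um = np.array([v / 1000.0 for v in params.voxel_size_nm])
    radii = np.asarray(params.nucleus_radii_um, float)
    shape = tuple(params.stack_shape)

    dna = np.full(shape, params.dna_levels[0], dtype=float)
    gh = np.full(shape, params.focus_bg[0], dtype=float)
    smc = np.full(shape, params.focus_bg[0], dtype=float)
    amp_gh = params.snr[0] * math.sqrt(params.focus_bg[1] + params.read_noise_sd**2)
    amp_smc = params.snr[1] * math.sqrt(params.focus_bg[1] + params.read_noise_sd**2)

    centers = _nucleus_centers(rng, params)
    nuclei: list[NucleusTruth] = []
    for label, c_vox in enumerate(centers, start=1):
        c_um = c_vox * voxel_um
        _add_ellipsoid(dna, c_vox, radii, voxel_um, params.dna_levels[1] - params.dna_levels[0])
        _add_ellipsoid(gh, c_vox, radii, voxel_um, params.focus_bg[1] - params.focus_bg[0])
        _add_ellipsoid(smc, c_vox, radii, voxel_um, params.focus_bg[1] - params.focus_bg[0])

        n_gh = _draw_count(rng, params.n_gh2ax_per_nucleus)
        n_extra = _draw_count(rng, params.extra_smc6)
        pts = _place_points_in_ellipsoid(
            rng, n_gh + n_extra, radii, params.min_sep_um
        )
        gh_pts = pts[:n_gh] + c_um
        extra_pts = pts[n_gh:] + c_um
        flags = rng.random(n_gh) < params.coloc_prob
        for p in gh_pts:
            _add_blob(gh, p, params.focus_sigma_um, voxel_um, amp_gh)
        for p in gh_pts[flags]:
            _add_blob(smc, p, params.focus_sigma_um, voxel_um, amp_smc)
        for p in extra_pts:
            _add_blob(smc, p, params.focus_sigma_um, voxel_um, amp_smc)
        nuclei.append(
            NucleusTruth(
                label=label,
                center_um=c_um,
                radii_um=radii.copy(),
                gh2ax_centers_um=gh_pts,
                coloc_flags=flags,
                smc6_only_centers_um=extra_pts,
            )
        )

    data = np.stack([dna, gh, smc])
    if params.noise:
        noisy = rng.poisson(np.clip(data, 0, None)).astype(float)
        noisy += rng.normal(0.0, params.read_noise_sd, size=data.shape)
        data = np.clip(noisy, 0.0, None)
    stack = ImageStack(
        data.astype(np.float32), params.voxel_size_nm, CHANNELS
    )
    return stack, GroundTruth(nuclei)


def gen_colony_counts(
    pe: float,
    alpha: float,
    beta: float,
    doses: Sequence[float],
    n_plated: Sequence[int],
    replicates: int = 3,
    seed: int | object = 0,
    genotype: str = "WT",
    agent: str = "IR",
    density_factors: Sequence[int] = (1, 2),
) -> pd.DataFrame:
    """Colony-count table under a linear-quadratic survival law.

    Colonies ~ Binomial(n_plated, pe * exp(-alpha*D - beta*D^2)), with each
    dose plated at two cell densities per experiment (the second density
    plates ``density_factors[1]`` times as many cells).
    """
    if not 0.0 < pe <= 1.0:
        raise ValueError("plating efficiency must be in (0, 1]")
    doses = list(doses)
    if any(d < 0 for d in doses):
        raise ValueError("doses must be >= 0")
    if len(n_plated) != len(doses):
        raise ValueError("n_plated must have one entry per dose")
    rng = np.random.default_rng(seed)
    rows = []
    for exp_id in range(1, replicates + 1):
        for dose, n0 in zip(doses, n_plated):
            surv = math.exp(-alpha * dose - beta * dose**2)
            p = min(pe * surv, 1.0)
            for dens in density_factors:
                n = int(n0) * int(dens)
                rows.append(
                    {
                        "experiment": exp_id,
                        "genotype": genotype,
                        "agent": agent,
                        "dose": float(dose),
                        "density": int(dens),
                        "cells_plated": n,
                        "colonies": int(rng.binomial(n, p)),
                    }
                )
    return pd.DataFrame(rows)


def gen_dna_histogram(
    frac_g01: float,
    frac_s: float,
    frac_g2m: float,
    cv: float = 0.04,
    arrested_frac: float = 0.0,
    n_events: int = 10_000,
    seed: int | object = 0,
    mu: float = 50.0,
    genotype: str = "",
    colcemid_h: float = 0.0,
) -> DNAContentSample:
    """DNA-content events from a G0/1-S-G2/M mixture.

    G0/1 events ~ Normal(mu, cv*mu), G2/M ~ Normal(2mu, cv*2mu), S uniform on
    (mu, 2mu) convolved with the same multiplicative noise.  ``arrested_frac``
    is an extra 2N subpopulation (e.g. colcemid-resistant, non-cycling cells)
    added on top of the cycling fractions, which must sum to 1.
    """
    fr = np.array([frac_g01, frac_s, frac_g2m], float)
    if np.any(fr < 0) or not math.isclose(fr.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("cycling fractions must be >= 0 and sum to 1")
    if not 0.0 <= arrested_frac <= 1.0:
        raise ValueError("arrested_frac must be in [0, 1]")
    if cv <= 0:
        raise ValueError("cv must be positive")
    rng = np.random.default_rng(seed)
    eff = np.empty(3)
    eff[0] = arrested_frac + (1 - arrested_frac) * fr[0]
    eff[1] = (1 - arrested_frac) * fr[1]
    eff[2] = (1 - arrested_frac) * fr[2]
    n1, ns, n2 = rng.multinomial(n_events, eff)
    g1 = rng.normal(mu, cv * mu, n1)
    u = rng.uniform(mu, 2 * mu, ns)
    s = u + rng.normal(0.0, cv * u)
    g2 = rng.normal(2 * mu, cv * 2 * mu, n2)
    values = rng.permutation(np.concatenate([g1, s, g2]))
    values = np.clip(values, 1e-6, None)
    return DNAContentSample(values=values, genotype=genotype, colcemid_h=colcemid_h)


def gen_colcemid_series(
    times_h: Sequence[float] = (0.0, 24.0, 48.0, 72.0, 96.0),
    f0: Sequence[float] = (0.5, 0.2, 0.3),
    residual: float = 0.16,
    tau_h: float = 12.0,
    cv: float = 0.04,
    n_events: int = 5000,
    seed: int | object = 0,
    mu: float = 50.0,
    genotype: str = "",
) -> list[DNAContentSample]:
    """DNA-content samples over a colcemid time course.

    The cycling G0/1 and S fractions decay with time constant ``tau_h`` while
    an arrested subpopulation of size ``residual`` stays at 2N; the displaced
    mass accumulates in G2/M (cells trapped in mitosis), so
    ``f_G01(t) = residual + (f0_g01 - residual) * exp(-t/tau)``.
    """
    f0 = np.asarray(f0, float)
    if not 0.0 <= residual <= f0[0]:
        raise ValueError("residual must be in [0, f0_g01]")
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    children = ss.spawn(len(times_h))
    samples = []
    for t, child in zip(times_h, children):
        decay = math.exp(-t / tau_h)
        f_g01 = residual + (f0[0] - residual) * decay
        f_s = f0[1] * decay
        f_g2m = 1.0 - f_g01 - f_s
        samples.append(
            gen_dna_histogram(
                f_g01, f_s, f_g2m, cv=cv, n_events=n_events, seed=child,
                mu=mu, genotype=genotype, colcemid_h=float(t),
            )
        )
    return samples


def gen_division_tracks(
    mean_wt: float = 17.0,
    fold: float = 1.37,
    cv: float = 0.15,
    n_cells: int = 50,
    n_generations: int = 6,
    seed: int | object = 0,
    lines: tuple[str, str] = ("WT", "null"),
) -> tuple[DivisionTracks, DivisionTracks]:
    """Lognormal division-interval tracks for two lines.

    The first line has mean interval ``mean_wt`` hours; the second line's
    mean is ``fold`` times longer.  Each of ``n_cells`` lineages contributes
    ``n_generations`` consecutive intervals.
    """
    if mean_wt <= 0 or fold <= 0 or cv < 0:
        raise ValueError("mean_wt and fold must be positive, cv non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for line, mean in zip(lines, (mean_wt, fold * mean_wt)):
        if cv == 0:
            intervals = np.full((n_cells, n_generations), mean)
        else:
            sig2 = math.log(1.0 + cv**2)
            mu_log = math.log(mean) - sig2 / 2.0
            intervals = rng.lognormal(mu_log, math.sqrt(sig2),
                                      size=(n_cells, n_generations))
        times = np.cumsum(intervals, axis=1)
        rows = []
        for lid in range(n_cells):
            for gen in range(n_generations):
                rows.append(
                    {
                        "lineage_id": lid,
                        "generation": gen + 1,
                        "division_time_h": times[lid, gen],
                        "interval_h": intervals[lid, gen],
                    }
                )
        out.append(DivisionTracks(line=line, table=pd.DataFrame(rows)))
    return out[0], out[1]


def make_edited_template(
    seed: int | object = 0,
    fwd_primer: str = crispr.SURVEYOR_FWD_PRIMER,
    rev_primer: str = crispr.SURVEYOR_REV_PRIMER,
    site: str | None = None,
    guide: str = crispr.NSMCE2_SG1,
    cut_offset: int = 304,
    amplicon_length: int = 417,
    flank: int = 60,
) -> str:
    """Synthetic stand-in for the targeted genomic region.

    Builds a random template that embeds the given primer pair and target
    ``site`` so that the PCR amplicon has the requested length and the
    guide's blunt cut falls ``cut_offset`` bp from the forward primer's 5'
    end.  The default site contains both overlapping exon-3 sgRNA
    protospacers with their PAMs.  This is a synthetic sequence, not the real
    locus.
    """
    if site is None:
        # sg1 + TGGTA completes sg2's protospacer; TGG / AGG are their PAMs.
        site = crispr.NSMCE2_SG1 + "TGGTA" + "AGG"
    guide_start = cut_offset - crispr.CUT_OFFSET
    rev_site = crispr.reverse_complement(rev_primer)
    if guide_start < len(fwd_primer):
        raise ValueError("cut_offset places the guide inside the forward primer")
    if guide_start + len(site) > amplicon_length - len(rev_site):
        raise ValueError("site overlaps the reverse-primer binding site")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    total = flank + amplicon_length + flank
    for _ in range(50):
        arr = rng.choice(bases, size=total)
        template = "".join(arr)
        template = (
            template[:flank]
            + fwd_primer
            + template[flank + len(fwd_primer) :]
        )
        gpos = flank + guide_start
        template = template[:gpos] + site + template[gpos + len(site) :]
        rpos = flank + amplicon_length - len(rev_site)
        template = template[:rpos] + rev_site + template[rpos + len(rev_site) :]
        try:
            product = crispr.in_silico_pcr(template, fwd_primer, rev_primer)
        except crispr.PCRError:
            continue
        hits = crispr.find_protospacer(product.sequence, guide)
        if product.length == amplicon_length and len(hits) == 1 and (
            hits[0].cut_site == cut_offset
        ):
            return template
    raise RuntimeError("failed to build a unique synthetic template")
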