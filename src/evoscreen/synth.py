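"""Seeded generators for every input the pipeline consumes.

The study's raw data are not deposited, so these generators stand in: they
produce toy genomes with gene models, EMS-biased heterozygous variant sets
with caller evidence fields, microfermentation plates from the shared
two-substrate forward model, Poisson read-depth tracks with optional CNV
segments, and linear scintillation calibration data — each deterministic
for a fixed seed, with independent per-well / per-variant substreams so a
layout change does not shift unrelated draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Gene, ToyGenome
from .kinetics import FermentationCurve, StrainParams, model_curve
from .uptake import UptakeSeries
from .variants import GenomeTrack, VariantRecord, VariantSet

__all__ = [
    "PlateLayout",
    "WellAssignment",
    "quadruplicate_layout",
    "gen_toy_genome",
    "gen_variant_set",
    "gen_plate",
    "gen_depth_track",
    "gen_uptake_assay",
    "curve_with_aucs",
]

_BASES = np.array(list("ACGT"))


def _substream(seed: int, *labels) -> np.random.Generator:
    """Derive an independent child stream from ``seed`` and string labels."""
    keys = [zlib.crc32(str(lab).encode()) for lab in labels]
    return np.random.default_rng([seed % 2**31, *keys])


# ---------------------------------------------------------------------------
# toy genome


def gen_toy_genome(
    n_chrom: int,
    chrom_len: int,
    n_genes: int,
    seed: int,
    gene_len_codons: tuple[int, int] = (30, 120),
    max_tries: int = 200,
) -> ToyGenome:
    """Random chromosomes with non-overlapping, frame-anchored genes.

    Gene lengths are a whole number of codons drawn from
    ``gene_len_codons``; placement retries up to ``max_tries`` per gene and
    raises when the requested genes cannot be packed.
    """
    if n_chrom < 1 or chrom_len < 3 or n_genes < 0:
        raise ValueError("need n_chrom ≥ 1, chrom_len ≥ 3, n_genes ≥ 0")
    rng = _substream(seed, "toy-genome")
    chromosomes = {
        f"chr{i + 1}": "".join(rng.choice(_BASES, size=chrom_len))
        for i in range(n_chrom)
    }
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chromosomes}
    genes: list[Gene] = []
    for gi in range(n_genes):
        placed = False
        for _ in range(max_tries):
            chrom = f"chr{rng.integers(1, n_chrom + 1)}"
            length = 3 * int(rng.integers(gene_len_codons[0], gene_len_codons[1] + 1))
            if length >= chrom_len:
                continue
            start = int(rng.integers(0, chrom_len - length))
            end = start + length
            if any(not (end <= a or start >= b) for a, b in occupied[chrom]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(f"gene{gi + 1:03d}", chrom, start, end, strand))
            occupied[chrom].append((start, end))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place gene {gi + 1}/{n_genes} after {max_tries} tries; "
                "genome too small for the requested gene count"
            )
    return ToyGenome(chromosomes=chromosomes, genes=genes)


# ---------------------------------------------------------------------------
# variant sets


# alts outside the EMS footprint: no C>T at C sites, no G>A at G sites
_NON_EMS_ALTS = {"A": "CGT", "C": "AG", "G": "CT", "T": "ACG"}


def _f32(x: float) -> float:
    # htslib stores INFO floats as float32 and prints 6 significant digits;
    # quantise to 2 decimals so generated values survive the round-trip exactly
    return float(np.float32(round(x, 2)))


def _passing_evidence(rng, zygosity: str) -> tuple[float, dict]:
    dp = 2 * int(rng.integers(30, 80))  # even, so het AF is exactly 0.5
    alt = dp if zygosity == "hom" else dp // 2
    ref = dp - alt
    saf, sar = alt // 2, alt - alt // 2
    srf, srr = ref // 2, ref - ref // 2
    qual = _f32(rng.uniform(50, 500))
    info = {
        "MQM": _f32(rng.uniform(40, 60)),
        "MQMR": _f32(rng.uniform(40, 60)),
        "DP": dp,
        "SAF": saf,
        "SAR": sar,
        "SRF": srf,
        "SRR": srr,
        "DP4": (srf, srr, saf, sar),
    }
    return qual, info


def _failing_evidence(rng, zygosity: str) -> tuple[float, dict]:
    qual, info = _passing_evidence(rng, zygosity)
    clause = rng.integers(0, 4)
    if clause == 0:
        qual = _f32(rng.uniform(0, 15))
    elif clause == 1:
        info["DP"] = int(rng.integers(5, 35))
    elif clause == 2:
        info["MQM"] = _f32(rng.uniform(5, 25))
    else:  # too few alt reads
        info["SAF"], info["SAR"] = 1, 1
        info["DP4"] = (info["SRF"], info["SRR"], 1, 1)
    return qual, info


def gen_variant_set(
    genome: ToyGenome,
    n: int,
    ems_fraction: float = 0.9,
    het_fraction: float = 0.97,
    pass_fraction: float = 1.0,
    seed: int = 0,
    n_indels: int = 0,
) -> VariantSet:
    """Draw ``n`` SNVs (plus optional indels) with an EMS-biased spectrum.

    A Bernoulli(``ems_fraction``) share are C>T / G>A at C/G reference
    sites; the rest are substitutions outside the EMS footprint.  Zygosity
    is Bernoulli(``het_fraction``) heterozygous, and evidence fields are
    drawn so that a Bernoulli(``pass_fraction``) share satisfies the
    freebayes hard-filter expression.  Heterozygous sites carry allele
    frequency exactly 0.5 and homozygous sites 1.0 in their strand counts.
    """
    for name, frac in (
        ("ems_fraction", ems_fraction),
        ("het_fraction", het_fraction),
        ("pass_fraction", pass_fraction),
    ):
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = _substream(seed, "variants")

    # index every site by reference base
    cg_sites: list[tuple[str, int]] = []
    at_sites: list[tuple[str, int]] = []
    for chrom, seq in genome.chromosomes.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        for pos0 in np.flatnonzero((arr == b"C") | (arr == b"G")):
            cg_sites.append((chrom, int(pos0)))
        for pos0 in np.flatnonzero((arr == b"A") | (arr == b"T")):
            at_sites.append((chrom, int(pos0)))

    is_ems = rng.random(n) < ems_fraction
    n_ems = int(is_ems.sum())
    if n_ems > len(cg_sites):
        raise ValueError(
            f"requested ~{n_ems} EMS variants but genome has only "
            f"{len(cg_sites)} C/G sites"
        )
    if n - n_ems > len(cg_sites) + len(at_sites) - n_ems:
        raise ValueError("more variants requested than available sites")

    ems_pool = [cg_sites[i] for i in rng.choice(len(cg_sites), n_ems, replace=False)]
    used = set(ems_pool)
    all_sites = cg_sites + at_sites
    other_pool: list[tuple[str, int]] = []
    order = rng.permutation(len(all_sites))
    for idx in order:
        if len(other_pool) == n - n_ems:
            break
        site = all_sites[idx]
        if site not in used:
            other_pool.append(site)
            used.add(site)

    records: list[VariantRecord] = []
    ems_iter = iter(ems_pool)
    other_iter = iter(other_pool)
    for i in range(n):
        if is_ems[i]:
            chrom, pos0 = next(ems_iter)
            ref = genome.chromosomes[chrom][pos0]
            alt = "T" if ref == "C" else "A"
        else:
            chrom, pos0 = next(other_iter)
            ref = genome.chromosomes[chrom][pos0]
            alt = _NON_EMS_ALTS[ref][rng.integers(0, len(_NON_EMS_ALTS[ref]))]
        zyg = "het" if rng.random() < het_fraction else "hom"
        vr_rng = _substream(seed, "evidence", chrom, pos0)
        if rng.random() < pass_fraction:
            qual, info = _passing_evidence(vr_rng, zyg)
        else:
            qual, info = _failing_evidence(vr_rng, zyg)
        records.append(
            VariantRecord(
                chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt, qual=qual,
                zygosity=zyg, caller="freebayes", info=info,
            )
        )

    for _ in range(n_indels):
        for _try in range(100):
            chrom = list(genome.chromosomes)[rng.integers(0, len(genome.chromosomes))]
            seq = genome.chromosomes[chrom]
            pos0 = int(rng.integers(0, len(seq) - 2))
            if (chrom, pos0) in used:
                continue
            used.add((chrom, pos0))
            break
        else:
            raise RuntimeError("could not place indel")
        anchor = seq[pos0]
        if rng.random() < 0.5:  # single-base insertion (frameshift)
            ref, alt = anchor, anchor + str(rng.choice(_BASES))
        else:  # single-base deletion
            ref, alt = seq[pos0 : pos0 + 2], anchor
        zyg = "het" if rng.random() < het_fraction else "hom"
        vr_rng = _substream(seed, "evidence", chrom, pos0)
        qual, info = _passing_evidence(vr_rng, zyg)
        records.append(
            VariantRecord(
                chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt, qual=qual,
                zygosity=zyg, caller="freebayes", info=info,
            )
        )

    return VariantSet(records).sorted()


# ---------------------------------------------------------------------------
# microfermentation plates


@dataclass(frozen=True)
class WellAssignment:
    plate: str
    well: str
    isolate: str
    role: str  # isolate / parent / MP / sterile


@dataclass
class PlateLayout:
    wells: list[WellAssignment] = field(default_factory=list)

    def isolate_ids(self) -> set[str]:
        return {w.isolate for w in self.wells if w.role != "sterile"}


def quadruplicate_layout(
    isolate_ids: list[str],
    plate: str,
    parent_id: str = "parent",
    mp_id: str = "MP",
    n_replicates: int = 4,
    sterile_wells: int = 1,
) -> PlateLayout:
    """Plate layout mirroring the screen: each quadrant replicates every
    isolate plus the parent and mixed-population controls, with sterile
    wells for contamination control."""
    wells = []
    for q in range(1, n_replicates + 1):
        idx = 1
        for iso in isolate_ids:
            wells.append(WellAssignment(plate, f"Q{q}-{idx:02d}", iso, "isolate"))
            idx += 1
        wells.append(WellAssignment(plate, f"Q{q}-{idx:02d}", parent_id, "parent"))
        wells.append(WellAssignment(plate, f"Q{q}-{idx + 1:02d}", mp_id, "MP"))
        for s in range(sterile_wells):
            wells.append(
                WellAssignment(plate, f"Q{q}-S{s + 1:02d}", "sterile", "sterile")
            )
    return PlateLayout(wells)


DEFAULT_T_GRID = np.arange(0.0, 169.0, 24.0)  # daily sacrificial sampling, h


def gen_plate(
    layout: PlateLayout,
    params_by_isolate: dict[str, StrainParams],
    glucose0: float = 50.0,
    fructose0: float = 50.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    t_grid: np.ndarray | None = None,
) -> list[FermentationCurve]:
    """Simulate every well of ``layout`` and add truncated Gaussian noise.

    Defaults mirror the screen medium (50 g l⁻¹ of each of glucose and
    fructose).  Each non-sterile well integrates the forward model for its
    isolate's parameters; plate noise is additive Gaussian truncated at zero
    (residual sugar cannot be negative), drawn from a per-well substream.
    """
    if glucose0 < 0 or fructose0 < 0:
        raise ValueError("initial sugars must be ≥ 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    t_grid = DEFAULT_T_GRID if t_grid is None else np.asarray(t_grid, dtype=float)

    needed = {w.isolate for w in layout.wells if w.role != "sterile"}
    unknown = needed - set(params_by_isolate)
    if unknown:
        raise KeyError(f"no StrainParams for isolates: {sorted(unknown)}")

    clean: dict[str, FermentationCurve] = {}
    for iso in sorted(needed):
        clean[iso] = model_curve(
            params_by_isolate[iso], glucose0, fructose0, t_grid, isolate=iso
        )

    curves = []
    for w in layout.wells:
        if w.role == "sterile":
            glu = np.full_like(t_grid, glucose0)
            fru = np.full_like(t_grid, fructose0)
        else:
            base = clean[w.isolate]
            glu, fru = base.glucose.copy(), base.fructose.copy()
        if noise_sd > 0:
            rng = _substream(seed, "plate", w.plate, w.well)
            glu = np.maximum(glu + rng.normal(0, noise_sd, size=len(t_grid)), 0.0)
            fru = np.maximum(fru + rng.normal(0, noise_sd, size=len(t_grid)), 0.0)
        curves.append(
            FermentationCurve(
                isolate=w.isolate, plate=w.plate, well=w.well, role=w.role,
                times=t_grid.copy(), glucose=glu, fructose=fru,
            )
        )
    return curves


def curve_with_aucs(
    auc_glu: float,
    auc_fru: float,
    t_end: float = 100.0,
    start: float = 50.0,
    isolate: str = "synthetic",
    plate: str = "P1",
    well: str = "A1",
    role: str = "isolate",
) -> FermentationCurve:
    """Piecewise-linear curves with exactly prescribed sugar AUCs.

    Each sugar starts at ``start`` and either declines linearly to zero
    before ``t_end`` (area < start·t_end/2) or declines linearly to a
    positive endpoint (larger areas).  Trapezoidal integration at the
    breakpoints recovers the requested areas exactly, which lets screen
    scenarios (target GLU/FRU and OFP ratios) be encoded in closed form.
    """
    max_area = start * t_end
    times: list[float] = [0.0]
    for area in (auc_glu, auc_fru):
        if not 0 < area <= max_area:
            raise ValueError(f"area {area} outside (0, {max_area}]")
        if area <= start * t_end / 2:
            times.append(2 * area / start)
    grid = np.unique(np.asarray(sorted(set(times + [t_end])), dtype=float))

    def series(area: float) -> np.ndarray:
        if area <= start * t_end / 2:
            t_zero = 2 * area / start
            return np.interp(grid, [0.0, t_zero, t_end], [start, 0.0, 0.0])
        v_end = 2 * area / t_end - start
        return np.interp(grid, [0.0, t_end], [start, v_end])

    return FermentationCurve(
        isolate=isolate, plate=plate, well=well, role=role,
        times=grid, glucose=series(auc_glu), fructose=series(auc_fru),
    )


# ---------------------------------------------------------------------------
# depth tracks


def gen_depth_track(
    genome: ToyGenome,
    mean_depth: float = 100.0,
    cnv_segments: list[tuple[str, int, int, float]] | None = None,
    window: int = 1000,
    seed: int = 0,
) -> GenomeTrack:
    """Per-window read depths, Poisson around mean_depth × copy ratio.

    ``cnv_segments`` are (chrom, start, end, copy_ratio) with 0-based
    half-open coordinates and copy_ratio > 0; a window takes a segment's
    ratio when its midpoint falls inside.
    """
    if mean_depth <= 0 or window <= 0:
        raise ValueError("mean_depth and window must be > 0")
    cnv_segments = cnv_segments or []
    for chrom, start, end, ratio in cnv_segments:
        if chrom not in genome.chromosomes:
            raise ValueError(f"CNV segment on unknown chromosome {chrom}")
        if not 0 <= start < end <= genome.chrom_length(chrom):
            raise ValueError(f"CNV segment [{start},{end}) outside {chrom}")
        if ratio <= 0:
            raise ValueError("copy_ratio must be > 0")
    rng = _substream(seed, "depth")
    rows = []
    for chrom in genome.chromosomes:
        length = genome.chrom_length(chrom)
        if window > length:
            raise ValueError(f"window {window} larger than {chrom} ({length} bp)")
        for start in range(0, length - window + 1, window):
            mid = start + window // 2
            ratio = 1.0
            for c, s, e, r in cnv_segments:
                if c == chrom and s <= mid < e:
                    ratio = r
                    break
            depth = int(rng.poisson(mean_depth * ratio))
            rows.append(
                {"chrom": chrom, "start": start, "end": start + window, "value": depth}
            )
    return GenomeTrack(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# uptake assay


def gen_uptake_assay(
    true_rate: float,
    calib_slope: float = 1e7,
    dcw: float = 2.0,
    times: list[float] | None = None,
    noise_cv: float = 0.05,
    seed: int = 0,
    background_cpm: float = 50.0,
    n_standards: int = 6,
    n_replicates: int = 1,
    strain: str = "strain",
) -> tuple[list[tuple[float, float]], list[UptakeSeries]]:
    """Calibration standards plus CPM series consistent with ``true_rate``.

    Cumulative uptake at time t is true_rate × t × dcw (nmol); counts are
    background + slope × nmol with multiplicative CV noise.  Standards span
    the series' CPM range.  The default grid is the assay's 20/60/150/300 s.
    """
    times = [20.0, 60.0, 150.0, 300.0] if times is None else list(times)
    if len(times) == 0:
        raise ValueError("times must be non-empty")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("times must be non-negative increasing")
    if true_rate < 0 or calib_slope <= 0 or dcw <= 0 or noise_cv < 0:
        raise ValueError("need true_rate ≥ 0, calib_slope > 0, dcw > 0, noise_cv ≥ 0")

    rng = _substream(seed, "uptake", strain)
    max_nmol = true_rate * t[-1] * dcw
    span = max_nmol * 1.5 if max_nmol > 0 else 1.0
    levels = np.linspace(0.0, span, n_standards)
    standards = []
    for lvl in levels:
        cpm = background_cpm + calib_slope * lvl
        cpm *= 1.0 + (noise_cv * rng.standard_normal() if noise_cv > 0 else 0.0)
        standards.append((float(lvl), float(max(cpm, 0.0))))

    series = []
    for rep in range(n_replicates):
        nmol = true_rate * t * dcw
        cpm = background_cpm + calib_slope * nmol
        if noise_cv > 0:
            cpm = cpm * (1.0 + noise_cv * rng.standard_normal(len(t)))
        series.append(
            UptakeSeries(times=t.copy(), cpm=np.maximum(cpm, 0.0), dcw=dcw,
                         strain=f"{strain}-r{rep + 1}" if n_replicates > 1 else strain)
        )
    return standards, series
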