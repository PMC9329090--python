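"""Post-calling variant QC: hard filters, EMS spectrum, consequences, LOH, CNV.

Implements the genome-analysis chain applied to the evolved isolate after
whole-genome sequencing:

* caller-specific hard-filter expressions (freebayes, LoFreq, GATK
  HaplotypeCaller), evaluated with strict inequalities exactly as written;
* the EMS mutational footprint — the fraction of single-nucleotide variants
  that are G/C→A/T transitions, the signature of ethyl methane sulfonate
  mutagenesis;
* zygosity accounting (EMS variants in a diploid are overwhelmingly
  heterozygous; homozygous runs hint at mitotic recombination);
* coding-consequence annotation over an intron-less toy genome
  (synonymous / missense / nonsense / frameshift / in-frame indel, with
  protein notation such as E726K or Q20*);
* allele-frequency tracks and automated loss-of-heterozygosity (LOH) run
  calling;
* windowed read-depth copy-number ratios normalised by the genome-wide mean
  depth, with deviant-run flagging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq

from .genome import Gene, ToyGenome

__all__ = [
    "VariantRecord",
    "VariantSet",
    "FilterResult",
    "Consequence",
    "GenomeTrack",
    "LohSegment",
    "CnvSegment",
    "read_vcf",
    "write_vcf",
    "filter_freebayes",
    "filter_lofreq",
    "filter_gatk",
    "apply_filters",
    "substitution_spectrum",
    "SpectrumResult",
    "zygosity_partition",
    "annotate_consequence",
    "allele_frequency_track",
    "call_loh_segments",
    "cnv_windows",
    "flag_cnv",
    "mutation_report",
]

CALLERS = ("freebayes", "lofreq", "gatk")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# INFO field typing for the VCF header (id -> (Number, Type))
_INFO_FIELDS = {
    "DP": (1, "Integer"),
    "MQM": (1, "Float"),
    "MQMR": (1, "Float"),
    "SAF": (1, "Integer"),
    "SAR": (1, "Integer"),
    "SRF": (1, "Integer"),
    "SRR": (1, "Integer"),
    "DP4": (4, "Integer"),
    "QD": (1, "Float"),
    "FS": (1, "Float"),
    "MQ": (1, "Float"),
    "MQRankSum": (1, "Float"),
    "ReadPosRankSum": (1, "Float"),
    "CALLER": (1, "String"),
}

# evidence keys normalised onto every record (None = absent-field marker)
EVIDENCE_KEYS = tuple(k for k in _INFO_FIELDS if k != "CALLER")


@dataclass
class VariantRecord:
    """One called variant with caller-specific evidence fields.

    ``pos`` is 1-based as in VCF.  Evidence fields live in ``info`` and may
    be absent; ``zygosity`` is "het" or "hom" (hom-alt).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    zygosity: str
    caller: str
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be ≥ 1 (VCF is 1-based)")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.zygosity not in ("het", "hom"):
            raise ValueError("zygosity must be 'het' or 'hom'")
        if self.caller not in CALLERS:
            raise ValueError(f"caller must be one of {CALLERS}")
        for key in EVIDENCE_KEYS:
            self.info.setdefault(key, None)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def allele_frequency(self) -> float:
        """Alternate-allele read fraction from the caller's evidence fields."""
        info = self.info
        if info.get("SAF") is not None and info.get("SAR") is not None and info.get("DP"):
            return (info["SAF"] + info["SAR"]) / info["DP"]
        if info.get("DP4") is not None:
            dp4 = info["DP4"]
            total = sum(dp4)
            if total == 0:
                raise ValueError("zero-depth DP4; allele frequency undefined")
            return (dp4[2] + dp4[3]) / total
        raise ValueError(
            f"{self.chrom}:{self.pos} lacks strand-count evidence for allele frequency"
        )


@dataclass
class VariantSet:
    """Ordered collection of variant records from one caller run."""

    records: list[VariantRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def snvs(self) -> list[VariantRecord]:
        return [r for r in self.records if r.is_snv]

    def indels(self) -> list[VariantRecord]:
        return [r for r in self.records if not r.is_snv]

    def sorted(self) -> "VariantSet":
        return VariantSet(sorted(self.records, key=lambda r: (r.chrom, r.pos, r.alt)))


# ---------------------------------------------------------------------------
# VCF I/O (pysam)


def _build_header(
    records: list[VariantRecord], contigs: dict[str, int] | None
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    if contigs is None:
        contigs = {}
        for r in records:
            end = r.pos + len(r.ref)
            contigs[r.chrom] = max(contigs.get(r.chrom, 0), end)
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for fid, (number, ftype) in _INFO_FIELDS.items():
        header.info.add(fid, number, ftype, f"{fid} evidence field")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample("SAMPLE")
    return header


def write_vcf(
    variant_set: VariantSet,
    path: str | Path,
    contigs: dict[str, int] | None = None,
    filters: dict[int, "FilterResult"] | None = None,
) -> None:
    """Write a VCF v4.2 (plain text, 1-based positions).

    ``filters`` optionally maps record index → :class:`FilterResult`; when
    given, the FILTER column is populated with PASS or the failure reasons.
    """
    header = _build_header(variant_set.records, contigs)
    if filters:
        seen: set[str] = set()
        for res in filters.values():
            for reason in res.reasons:
                fid = _filter_id(reason)
                if fid not in seen:
                    header.filters.add(fid, None, None, reason)
                    seen.add(fid)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, r in enumerate(variant_set.records):
            rec = out.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                alleles=(r.ref, r.alt),
                qual=r.qual,
            )
            for key, value in r.info.items():
                if value is not None:
                    rec.info[key] = value
            rec.info["CALLER"] = r.caller
            rec.samples["SAMPLE"]["GT"] = (0, 1) if r.zygosity == "het" else (1, 1)
            if filters is not None and i in filters:
                res = filters[i]
                if res.passed:
                    rec.filter.add("PASS")
                else:
                    for reason in res.reasons:
                        rec.filter.add(_filter_id(reason))
            out.write(rec)


def _filter_id(reason: str) -> str:
    return (
        reason.replace(" ", "_").replace(">", "gt").replace("<", "lt")
        .replace("(", "").replace(")", "").replace("/", "_").replace(":", "_")
        .replace("+", "plus").replace("≤", "le").replace("Σ", "sum").replace("=", "eq")
    )


def _scalar(value):
    """pysam returns 1-field INFO values as 1-tuples; unwrap them."""
    if isinstance(value, tuple) and len(value) == 1:
        return value[0]
    return value


def _info_get(rec, key):
    """INFO lookup tolerant of keys the header never declares."""
    try:
        if key in rec.info:
            return rec.info[key]
    except (KeyError, ValueError):
        pass
    return None


def read_vcf(path: str | Path, default_caller: str = "freebayes") -> VariantSet:
    """Read a VCF; multi-allelic records are split into one record per alt."""
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for line_no, rec in enumerate(vcf, start=1):
            caller = _scalar(_info_get(rec, "CALLER")) or default_caller
            zygosity = "het"
            if rec.samples:
                gt = rec.samples[0].get("GT")
                if gt is not None and None not in gt and len(set(gt)) == 1 and gt[0] != 0:
                    zygosity = "hom"
            info = {}
            for key in EVIDENCE_KEYS:
                value = _info_get(rec, key)
                if value is None:
                    info[key] = None
                elif key == "DP4":
                    info[key] = tuple(int(v) for v in value)
                else:
                    info[key] = _scalar(value)
            for alt in rec.alts or ():
                try:
                    records.append(
                        VariantRecord(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            qual=float(rec.qual) if rec.qual is not None else 0.0,
                            zygosity=zygosity,
                            caller=str(caller),
                            info=dict(info),
                        )
                    )
                except ValueError as exc:
                    raise ValueError(f"{path}: record {line_no}: {exc}") from exc
    return VariantSet(records)


# ---------------------------------------------------------------------------
# hard-filter engine


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reasons: tuple[str, ...] = ()


def _require(info: dict, fields: list[str]) -> list[str]:
    return [f"missing:{f}" for f in fields if info.get(f) is None]


def filter_freebayes(r: VariantRecord) -> FilterResult:
    """Freebayes hard filter:

    ``MQM>30 & MQMR>30 & QUAL>20 & INFO/DP>40 & (SAF+SAR)>4
    & (SRF+SAF)/(INFO/DP)>0.01 & (SRR+SAR)/(INFO/DP)>0.01``

    All inequalities strict; a missing required field fails the record.
    """
    if r.caller != "freebayes":
        raise ValueError(f"record tagged {r.caller!r}, expected freebayes")
    missing = _require(r.info, ["MQM", "MQMR", "DP", "SAF", "SAR", "SRF", "SRR"])
    if missing:
        return FilterResult(False, tuple(missing))
    i = r.info
    reasons = []
    if not i["MQM"] > 30:
        reasons.append("MQM<=30")
    if not i["MQMR"] > 30:
        reasons.append("MQMR<=30")
    if not r.qual > 20:
        reasons.append("QUAL<=20")
    if not i["DP"] > 40:
        reasons.append("DP<=40")
    if not (i["SAF"] + i["SAR"]) > 4:
        reasons.append("(SAF+SAR)<=4")
    if not (i["SRF"] + i["SAF"]) / i["DP"] > 0.01:
        reasons.append("(SRF+SAF)/DP<=0.01")
    if not (i["SRR"] + i["SAR"]) / i["DP"] > 0.01:
        reasons.append("(SRR+SAR)/DP<=0.01")
    return FilterResult(not reasons, tuple(reasons))


def filter_lofreq(r: VariantRecord) -> FilterResult:
    """LoFreq hard filter:

    ``QUAL>20 & DP>20 & (DP4[2]+DP4[3])>4`` plus strand-fraction clauses
    ``(DP4[0]+DP4[2])/ΣDP4>0.01`` and ``(DP4[1]+DP4[3])/ΣDP4>0.01``.
    """
    if r.caller != "lofreq":
        raise ValueError(f"record tagged {r.caller!r}, expected lofreq")
    missing = _require(r.info, ["DP", "DP4"])
    if missing:
        return FilterResult(False, tuple(missing))
    dp4 = r.info["DP4"]
    total = sum(dp4)
    if total == 0:
        return FilterResult(False, ("zero-depth",))
    reasons = []
    if not r.qual > 20:
        reasons.append("QUAL<=20")
    if not r.info["DP"] > 20:
        reasons.append("DP<=20")
    if not (dp4[2] + dp4[3]) > 4:
        reasons.append("altreads<=4")
    if not (dp4[0] + dp4[2]) / total > 0.01:
        reasons.append("fwdfrac<=0.01")
    if not (dp4[1] + dp4[3]) / total > 0.01:
        reasons.append("revfrac<=0.01")
    return FilterResult(not reasons, tuple(reasons))


def filter_gatk(r: VariantRecord) -> FilterResult:
    """GATK HaplotypeCaller exclusion rule: the record FAILS iff

    ``QD < 2.0 || FS > 60.0 || MQ < 40.0 || MQRankSum < -12.5
    || ReadPosRankSum < -8.0``

    Absent annotations do not trigger their clause (GATK convention).
    """
    if r.caller != "gatk":
        raise ValueError(f"record tagged {r.caller!r}, expected gatk")
    i = r.info
    reasons = []
    if i.get("QD") is not None and i["QD"] < 2.0:
        reasons.append("QD<2.0")
    if i.get("FS") is not None and i["FS"] > 60.0:
        reasons.append("FS>60.0")
    if i.get("MQ") is not None and i["MQ"] < 40.0:
        reasons.append("MQ<40.0")
    if i.get("MQRankSum") is not None and i["MQRankSum"] < -12.5:
        reasons.append("MQRankSum<-12.5")
    if i.get("ReadPosRankSum") is not None and i["ReadPosRankSum"] < -8.0:
        reasons.append("ReadPosRankSum<-8.0")
    return FilterResult(not reasons, tuple(reasons))


_FILTERS = {"freebayes": filter_freebayes, "lofreq": filter_lofreq, "gatk": filter_gatk}


def apply_filters(variant_set: VariantSet) -> dict[int, FilterResult]:
    """Evaluate the caller-appropriate filter on every record."""
    return {
        i: _FILTERS[r.caller](r) for i, r in enumerate(variant_set.records)
    }


# ---------------------------------------------------------------------------
# mutational spectrum & zygosity


@dataclass(frozen=True)
class SpectrumResult:
    """SNV substitution classes with purines mirrored onto pyrimidines."""

    counts: dict[str, int]
    n_snv: int
    ems_count: int  # raw C>T at C sites + G>A at G sites
    ems_fraction: float | None  # None for an empty SNV set


def substitution_spectrum(variant_set: VariantSet) -> SpectrumResult:
    """Classify SNVs into the six pyrimidine-anchored substitution classes.

    G>A mirrors to C>T, etc., so strand flipping leaves class counts
    unchanged.  The EMS footprint is the fraction of SNVs that are G/C→A/T
    transitions (C>T at C reference sites plus G>A at G sites).
    """
    counts = {c: 0 for c in ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")}
    ems = 0
    snvs = variant_set.snvs()
    for r in snvs:
        ref, alt = r.ref.upper(), r.alt.upper()
        if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
            raise ValueError(f"non-ACGT allele in SNV {r.chrom}:{r.pos} {ref}>{alt}")
        if ref in ("G", "A"):
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        counts[f"{ref}>{alt}"] += 1
        if (r.ref.upper(), r.alt.upper()) in (("C", "T"), ("G", "A")):
            ems += 1
    n = len(snvs)
    return SpectrumResult(
        counts=counts, n_snv=n, ems_count=ems,
        ems_fraction=(ems / n) if n else None,
    )


def zygosity_partition(
    variant_set: VariantSet,
) -> tuple[int, int, list[tuple[str, int]]]:
    """Return (n_het, n_hom, sorted homozygous positions)."""
    hom = sorted(
        (r.chrom, r.pos) for r in variant_set if r.zygosity == "hom"
    )
    n_hom = len(hom)
    return len(variant_set) - n_hom, n_hom, hom


# ---------------------------------------------------------------------------
# consequence annotation


@dataclass(frozen=True)
class Consequence:
    gene_id: str | None
    csq_class: str  # noncoding/synonymous/missense/nonsense/frameshift/inframe-indel
    protein_notation: str | None


def _overlapping_gene(r: VariantRecord, genome: ToyGenome) -> Gene | None:
    span_start = r.pos - 1
    span_end = span_start + len(r.ref)
    hit: Gene | None = None
    for g in genome.genes:
        if g.chrom != r.chrom:
            continue
        if span_end <= g.start or span_start >= g.end:
            continue
        inside = span_start >= g.start and span_end <= g.end
        if not inside:
            raise ValueError(
                f"variant {r.chrom}:{r.pos} {r.ref}>{r.alt} overlaps the boundary "
                f"of {g.gene_id}; boundary-spanning variants are unsupported"
            )
        hit = g
    return hit


def annotate_consequence(r: VariantRecord, genome: ToyGenome) -> Consequence:
    """Classify a variant against the toy genome's single-CDS gene models.

    In-CDS SNVs are translated on the coding strand via the standard codon
    table; protein notation follows the E726K / Q20* convention.  Indels are
    frameshift when the length change is not a multiple of 3, in-frame
    otherwise.  Intergenic variants are noncoding.
    """
    if r.chrom not in genome.chromosomes:
        raise ValueError(f"unknown chromosome {r.chrom}")
    gene = _overlapping_gene(r, genome)
    if gene is None:
        return Consequence(None, "noncoding", None)

    cds = genome.coding_sequence(gene)
    pos0 = r.pos - 1
    if r.is_snv:
        ref_base = genome.chromosomes[r.chrom][pos0]
        if ref_base != r.ref.upper():
            raise ValueError(
                f"reference mismatch at {r.chrom}:{r.pos}: genome has {ref_base}, "
                f"record claims {r.ref}"
            )
        if gene.strand == "+":
            offset = pos0 - gene.start
            alt_base = r.alt.upper()
        else:
            offset = gene.end - 1 - pos0
            alt_base = _COMPLEMENT[r.alt.upper()]
        codon_i, within = divmod(offset, 3)
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        mutated = codon[:within] + alt_base + codon[within + 1 :]
        ref_aa = str(Seq(codon).translate())
        alt_aa = str(Seq(mutated).translate())
        notation = f"{ref_aa}{codon_i + 1}{alt_aa}"
        if alt_aa == ref_aa:
            cls = "synonymous"
        elif alt_aa == "*":
            cls = "nonsense"
        else:
            cls = "missense"
        return Consequence(gene.gene_id, cls, notation)

    # indel
    length_change = len(r.alt) - len(r.ref)
    if gene.strand == "+":
        offset = pos0 - gene.start
    else:
        offset = gene.end - 1 - pos0
    codon_i = offset // 3
    ref_aa = str(Seq(cds[codon_i * 3 : codon_i * 3 + 3]).translate())
    if length_change % 3 != 0:
        return Consequence(gene.gene_id, "frameshift", f"{ref_aa}{codon_i + 1}fs")
    return Consequence(gene.gene_id, "inframe-indel", f"{ref_aa}{codon_i + 1}delins")


# ---------------------------------------------------------------------------
# genome tracks, LOH, CNV


@dataclass
class GenomeTrack:
    """Positionally indexed values: per-site (AF) or per-window (copy ratio).

    Intervals are 0-based half-open; a site occupies ``[pos0, pos0+1)``.
    """

    df: pd.DataFrame  # columns chrom, start, end, value

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "value"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"track needs columns {sorted(required)}")
        self.df = (
            self.df.sort_values(["chrom", "start"]).reset_index(drop=True)
        )
        for chrom, grp in self.df.groupby("chrom"):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping intervals on {chrom}")

    def __len__(self) -> int:
        return len(self.df)

    def values(self) -> np.ndarray:
        return self.df["value"].to_numpy()

    def write_bed(self, path: str | Path) -> None:
        self.df[["chrom", "start", "end", "value"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    @classmethod
    def read_bed(cls, path: str | Path) -> "GenomeTrack":
        df = pd.read_csv(
            path, sep="\t", names=["chrom", "start", "end", "value"], header=None
        )
        return cls(df)


def allele_frequency_track(variant_set: VariantSet) -> GenomeTrack:
    """Per-site alternate-allele read fractions, sorted by position."""
    rows = []
    for r in variant_set.sorted():
        af = r.allele_frequency()
        if not 0 <= af <= 1:
            raise ValueError(f"AF {af} outside [0,1] at {r.chrom}:{r.pos}")
        rows.append({"chrom": r.chrom, "start": r.pos - 1, "end": r.pos, "value": af})
    return GenomeTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))


@dataclass(frozen=True)
class LohSegment:
    chrom: str
    start: int  # 0-based half-open over the site run
    end: int
    n_sites: int
    mean_af: float
    state: str  # "hom-ref-run" / "hom-alt-run"


def call_loh_segments(
    track: GenomeTrack,
    hom_low: float = 0.1,
    hom_high: float = 0.9,
    min_sites: int = 6,
) -> list[LohSegment]:
    """Call loss-of-heterozygosity runs from a per-site AF track.

    A segment is a maximal run of ≥ ``min_sites`` consecutive sites that are
    all ≤ ``hom_low`` (hom-ref) or all ≥ ``hom_high`` (hom-alt); any
    intermediate-AF site or chromosome boundary breaks the run.  Defaults
    (0.1 / 0.9 / 6 sites) are motivated by the six-SNP homozygous run
    observed on chromosome XIII of the evolved isolate.
    """
    if not 0 <= hom_low < hom_high <= 1:
        raise ValueError("need 0 ≤ hom_low < hom_high ≤ 1")
    if min_sites < 1:
        raise ValueError("min_sites must be ≥ 1")

    segments: list[LohSegment] = []
    for chrom, grp in track.df.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        afs = grp["value"].to_numpy()
        states = np.where(
            afs <= hom_low, "hom-ref-run", np.where(afs >= hom_high, "hom-alt-run", "")
        )
        i = 0
        n = len(afs)
        while i < n:
            if states[i] == "":
                i += 1
                continue
            j = i
            while j + 1 < n and states[j + 1] == states[i]:
                j += 1
            if j - i + 1 >= min_sites:
                segments.append(
                    LohSegment(
                        chrom=str(chrom),
                        start=int(starts[i]),
                        end=int(ends[j]),
                        n_sites=j - i + 1,
                        mean_af=float(np.mean(afs[i : j + 1])),
                        state=str(states[i]),
                    )
                )
            i = j + 1
    return segments


@dataclass(frozen=True)
class CnvSegment:
    chrom: str
    start: int
    end: int
    n_windows: int
    mean_ratio: float
    direction: str  # "gain" / "loss"


def cnv_windows(depth: GenomeTrack, window: int = 1000) -> GenomeTrack:
    """Normalise a per-window depth track by the genome-wide mean depth.

    Mirrors the 1000-bp sliding-window copy-number method: each window's
    value becomes window depth / mean depth, so a CNV-free genome averages
    exactly 1 by construction.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    mean_depth = float(np.mean(depth.values()))
    if mean_depth == 0:
        raise ValueError("zero genome-wide mean depth; cannot normalise")
    df = depth.df.copy()
    df["value"] = df["value"] / mean_depth
    return GenomeTrack(df)


def flag_cnv(
    track: GenomeTrack, lo: float = 0.6, hi: float = 1.4, min_windows: int = 1
) -> list[CnvSegment]:
    """Flag maximal runs of windows with copy ratio outside [lo, hi]."""
    if not lo < hi:
        raise ValueError("need lo < hi")
    segments: list[CnvSegment] = []
    for chrom, grp in track.df.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        vals = grp["value"].to_numpy()
        states = np.where(vals > hi, "gain", np.where(vals < lo, "loss", ""))
        i = 0
        n = len(vals)
        while i < n:
            if states[i] == "":
                i += 1
                continue
            j = i
            while j + 1 < n and states[j + 1] == states[i]:
                j += 1
            if j - i + 1 >= min_windows:
                segments.append(
                    CnvSegment(
                        chrom=str(chrom),
                        start=int(starts[i]),
                        end=int(ends[j]),
                        n_windows=j - i + 1,
                        mean_ratio=float(np.mean(vals[i : j + 1])),
                        direction=str(states[i]),
                    )
                )
            i = j + 1
    return segments


# ---------------------------------------------------------------------------
# summary report


def mutation_report(variant_set: VariantSet, genome: ToyGenome) -> dict:
    """Internally consistent mutation summary.

    noncoding + coding = total; consequence class counts sum to the coding
    count; zygosity and spectrum are included alongside the mutated-gene and
    substitution-carrying gene sets.
    """
    consequences = [annotate_consequence(r, genome) for r in variant_set]
    class_counts = {
        c: 0 for c in (
            "synonymous", "missense", "nonsense", "frameshift", "inframe-indel"
        )
    }
    genes_mutated: set[str] = set()
    genes_nonsyn: set[str] = set()
    genes_syn: set[str] = set()
    noncoding = 0
    for csq in consequences:
        if csq.csq_class == "noncoding":
            noncoding += 1
            continue
        class_counts[csq.csq_class] += 1
        genes_mutated.add(csq.gene_id)
        if csq.csq_class in ("missense", "nonsense", "frameshift", "inframe-indel"):
            genes_nonsyn.add(csq.gene_id)
        else:
            genes_syn.add(csq.gene_id)
    n_het, n_hom, hom_positions = zygosity_partition(variant_set)
    spectrum = substitution_spectrum(variant_set)
    total = len(variant_set)
    coding = total - noncoding
    assert sum(class_counts.values()) == coding
    return {
        "total": total,
        "noncoding": noncoding,
        "coding": coding,
        "n_snv": len(variant_set.snvs()),
        "n_indel": len(variant_set.indels()),
        "consequence_counts": class_counts,
        "n_het": n_het,
        "n_hom": n_hom,
        "hom_positions": hom_positions,
        "spectrum": spectrum,
        "genes_mutated": sorted(genes_mutated),
        "genes_with_nonsyn": sorted(genes_nonsyn),
        "genes_with_syn_only": sorted(genes_syn - genes_nonsyn),
    }
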