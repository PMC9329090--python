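"""Hard filters, EMS spectrum, consequences, AF/LOH/CNV tracks, reports."""

import numpy as np
import pandas as pd
import pytest

import evoscreen as ev
from evoscreen.genome import Gene, ToyGenome
from evoscreen.variants import FilterResult, GenomeTrack, VariantRecord, VariantSet


def vrec(caller="freebayes", chrom="chr1", pos=100, ref="C", alt="T",
         qual=100.0, zygosity="het", **info):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual,
                         zygosity=zygosity, caller=caller, info=info)


# ---------------------------------------------------------------------------
# filter engines


class TestFreebayesFilter:
    BASE = dict(MQM=60.0, MQMR=60.0, DP=100, SAF=10, SAR=10, SRF=40, SRR=40)

    def test_clean_record_passes(self):
        assert ev.filter_freebayes(vrec(**self.BASE)).passed

    @pytest.mark.parametrize(
        "override, qual",
        [
            (dict(), 20.0),  # QUAL boundary: strict >
            (dict(MQM=30.0), 100.0),
            (dict(DP=40), 100.0),
            (dict(SAF=4, SAR=0), 100.0),  # (SAF+SAR) = 4 not > 4
        ],
    )
    def test_boundaries_fail_strictly(self, override, qual):
        fields = {**self.BASE, **override}
        res = ev.filter_freebayes(vrec(qual=qual, **fields))
        assert not res.passed and res.reasons

    def test_missing_field_fails_with_reason(self):
        fields = {k: v for k, v in self.BASE.items() if k != "DP"}
        res = ev.filter_freebayes(vrec(**fields))
        assert not res.passed
        assert "missing:DP" in res.reasons

    def test_wrong_caller_rejected(self):
        with pytest.raises(ValueError):
            ev.filter_freebayes(vrec(caller="lofreq", DP4=(1, 1, 1, 1), DP=10))


class TestLofreqFilter:
    def test_balanced_record_passes(self):
        r = vrec(caller="lofreq", qual=50.0, DP=100, DP4=(40, 40, 10, 10))
        assert ev.filter_lofreq(r).passed

    def test_one_sided_strand_fails_reverse_fraction(self):
        # all reads forward: reverse fraction 0/104 = 0, not > 0.01
        r = vrec(caller="lofreq", qual=50.0, DP=110, DP4=(99, 0, 5, 0))
        res = ev.filter_lofreq(r)
        assert not res.passed and "revfrac<=0.01" in res.reasons

    def test_qual_boundary(self):
        r = vrec(caller="lofreq", qual=20.0, DP=100, DP4=(40, 40, 10, 10))
        assert not ev.filter_lofreq(r).passed

    def test_zero_depth(self):
        r = vrec(caller="lofreq", qual=50.0, DP=100, DP4=(0, 0, 0, 0))
        assert ev.filter_lofreq(r).reasons == ("zero-depth",)


class TestGatkFilter:
    def test_benign_annotations_pass(self):
        r = vrec(caller="gatk", QD=10.0, FS=1.0, MQ=60.0,
                 MQRankSum=0.0, ReadPosRankSum=0.0)
        assert ev.filter_gatk(r).passed

    def test_low_qd_fails(self):
        r = vrec(caller="gatk", QD=1.9, FS=1.0, MQ=60.0)
        res = ev.filter_gatk(r)
        assert not res.passed and res.reasons == ("QD<2.0",)

    def test_absent_annotation_does_not_fire(self):
        r = vrec(caller="gatk", QD=10.0, FS=1.0, MQ=60.0)  # no RankSums
        assert ev.filter_gatk(r).passed


def _oracle_freebayes(r):
    i = r.info
    need = ["MQM", "MQMR", "DP", "SAF", "SAR", "SRF", "SRR"]
    if any(i.get(k) is None for k in need):
        return False
    return (
        i["MQM"] > 30 and i["MQMR"] > 30 and r.qual > 20 and i["DP"] > 40
        and (i["SAF"] + i["SAR"]) > 4
        and (i["SRF"] + i["SAF"]) / i["DP"] > 0.01
        and (i["SRR"] + i["SAR"]) / i["DP"] > 0.01
    )


def _oracle_lofreq(r):
    dp4 = r.info.get("DP4")
    if dp4 is None or r.info.get("DP") is None or sum(dp4) == 0:
        return False
    tot = sum(dp4)
    return (
        r.qual > 20 and r.info["DP"] > 20 and (dp4[2] + dp4[3]) > 4
        and (dp4[0] + dp4[2]) / tot > 0.01 and (dp4[1] + dp4[3]) / tot > 0.01
    )


def _oracle_gatk(r):
    i = r.info
    def bad(key, op, thresh):
        return i.get(key) is not None and op(i[key], thresh)
    import operator as O
    return not (
        bad("QD", O.lt, 2.0) or bad("FS", O.gt, 60.0) or bad("MQ", O.lt, 40.0)
        or bad("MQRankSum", O.lt, -12.5) or bad("ReadPosRankSum", O.lt, -8.0)
    )


def random_record(rng):
    """Adversarial draw concentrating mass near every clause boundary."""
    caller = rng.choice(["freebayes", "lofreq", "gatk"])
    qual = float(rng.choice([0.0, 15.0, 20.0, 20.01, 25.0, rng.uniform(0, 300)]))
    info = {}
    if caller == "freebayes":
        for k in ("MQM", "MQMR"):
            if rng.random() < 0.9:
                info[k] = float(rng.choice([10.0, 30.0, 30.5, rng.uniform(0, 70)]))
        if rng.random() < 0.9:
            info["DP"] = int(rng.choice([40, 41, 100, rng.integers(1, 200)]))
        for k in ("SAF", "SAR", "SRF", "SRR"):
            if rng.random() < 0.9:
                info[k] = int(rng.choice([0, 1, 2, 4, rng.integers(0, 60)]))
    elif caller == "lofreq":
        if rng.random() < 0.9:
            info["DP"] = int(rng.choice([20, 21, rng.integers(1, 200)]))
        if rng.random() < 0.9:
            info["DP4"] = tuple(
                int(rng.choice([0, 1, 4, 5, rng.integers(0, 80)])) for _ in range(4)
            )
    else:
        for k, vals in (
            ("QD", [1.9, 2.0, 2.1, 10.0]), ("FS", [59.0, 60.0, 61.0, 1.0]),
            ("MQ", [39.0, 40.0, 41.0, 60.0]), ("MQRankSum", [-13.0, -12.5, 0.0]),
            ("ReadPosRankSum", [-9.0, -8.0, 0.0]),
        ):
            if rng.random() < 0.7:
                info[k] = float(rng.choice(vals))
    return vrec(caller=caller, qual=qual, **info)


def test_filter_engines_agree_with_brute_force_oracle():
    """Engine pass/fail equals independent re-evaluation of the boolean
    expressions on thousands of boundary-heavy random records."""
    rng = np.random.default_rng(123)
    oracles = {"freebayes": _oracle_freebayes, "lofreq": _oracle_lofreq,
               "gatk": _oracle_gatk}
    engines = {"freebayes": ev.filter_freebayes, "lofreq": ev.filter_lofreq,
               "gatk": ev.filter_gatk}
    for _ in range(3000):
        r = random_record(rng)
        assert engines[r.caller](r).passed == oracles[r.caller](r), r


# ---------------------------------------------------------------------------
# spectrum & zygosity


class TestSpectrum:
    def test_direct_count(self):
        records = [
            vrec(pos=1, ref="C", alt="T"),
            vrec(pos=2, ref="G", alt="A"),
            vrec(pos=3, ref="A", alt="T"),
        ]
        sp = ev.substitution_spectrum(VariantSet(records))
        assert sp.ems_count == 2
        assert sp.ems_fraction == pytest.approx(2 / 3)
        assert sp.counts["C>T"] == 2 and sp.counts["T>A"] == 1

    def test_empty_set(self):
        sp = ev.substitution_spectrum(VariantSet([]))
        assert sp.n_snv == 0 and sp.ems_fraction is None
        assert all(v == 0 for v in sp.counts.values())

    def test_indels_excluded(self):
        records = [vrec(pos=1, ref="C", alt="T"), vrec(pos=2, ref="CT", alt="C")]
        sp = ev.substitution_spectrum(VariantSet(records))
        assert sp.n_snv == 1

    def test_strand_mirroring_invariance(self):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rng = np.random.default_rng(2)
        records = []
        for i in range(200):
            ref = rng.choice(list("ACGT"))
            alt = rng.choice([b for b in "ACGT" if b != ref])
            records.append(vrec(pos=i + 1, ref=ref, alt=alt))
        mirrored = [
            vrec(pos=r.pos, ref=comp[r.ref], alt=comp[r.alt]) for r in records
        ]
        sp1 = ev.substitution_spectrum(VariantSet(records))
        sp2 = ev.substitution_spectrum(VariantSet(mirrored))
        assert sp1.counts == sp2.counts
        assert sp1.ems_count == sp2.ems_count

    def test_non_acgt_allele_rejected(self):
        with pytest.raises(ValueError):
            ev.substitution_spectrum(VariantSet([vrec(ref="N", alt="T")]))


class TestZygosity:
    def test_all_het(self):
        vs = VariantSet([vrec(pos=i + 1) for i in range(5)])
        assert ev.zygosity_partition(vs) == (5, 0, [])

    def test_single_hom_position_returned(self):
        vs = VariantSet([vrec(pos=10), vrec(pos=7, zygosity="hom")])
        n_het, n_hom, hom = ev.zygosity_partition(vs)
        assert (n_het, n_hom) == (1, 1)
        assert hom == [("chr1", 7)]


# ---------------------------------------------------------------------------
# consequence annotation


@pytest.fixture(scope="module")
def crafted_genome():
    """One plus-strand gene with known codons and one minus-strand gene.

    Plus gene (chrA:10-460): codon 20 is CAA (Q), codon 135 is GGT (G), all
    other codons CTG (L).  Minus gene (chrA:500-530) encodes MQG LLL LLL *
    on the minus strand.
    """
    codons = ["CTG"] * 150
    codons[19] = "CAA"
    codons[134] = "GGT"
    plus_cds = "".join(codons)
    minus_cds = "ATGCAAGGT" + "CTG" * 6 + "TAA"
    from Bio.Seq import Seq

    minus_on_genome = str(Seq(minus_cds).reverse_complement())
    chrom = "A" * 10 + plus_cds + "A" * 40 + minus_on_genome + "A" * 70
    # layout: plus gene at [10, 460); minus gene at [500, 530)
    assert chrom[500:530] == minus_on_genome
    genome = ToyGenome(
        chromosomes={"chrA": chrom},
        genes=[
            Gene("plus_gene", "chrA", 10, 460, "+"),
            Gene("minus_gene", "chrA", 500, 530, "-"),
        ],
    )
    return genome


class TestConsequence:
    def test_nonsense_q20_star(self, crafted_genome):
        # CAA→TAA at codon 20: premature stop, Q20*
        r = vrec(chrom="chrA", pos=10 + 19 * 3 + 1, ref="C", alt="T")
        csq = ev.annotate_consequence(r, crafted_genome)
        assert csq.csq_class == "nonsense"
        assert csq.protein_notation == "Q20*"
        assert csq.gene_id == "plus_gene"

    def test_missense_g135s(self, crafted_genome):
        # GGT→AGT at codon 135: G135S
        r = vrec(chrom="chrA", pos=10 + 134 * 3 + 1, ref="G", alt="A")
        csq = ev.annotate_consequence(r, crafted_genome)
        assert csq.csq_class == "missense"
        assert csq.protein_notation == "G135S"

    def test_synonymous_third_position(self, crafted_genome):
        # CTG→CTT still leucine
        r = vrec(chrom="chrA", pos=10 + 2 + 1, ref="G", alt="T")
        csq = ev.annotate_consequence(r, crafted_genome)
        assert csq.csq_class == "synonymous"
        assert csq.protein_notation == "L1L"

    def test_synonymous_fixture_never_reports_protein_change(self, crafted_genome):
        """Third-position CTG→CTA/CTT/CTC edits across the gene stay silent."""
        for codon_i in (1, 5, 50, 100, 149):
            if codon_i in (19, 134):
                continue
            pos = 10 + codon_i * 3 + 2 + 1  # third base of a CTG codon
            for alt in "ATC":
                csq = ev.annotate_consequence(
                    vrec(chrom="chrA", pos=pos, ref="G", alt=alt), crafted_genome
                )
                assert csq.csq_class == "synonymous"
                assert csq.protein_notation[0] == csq.protein_notation[-1]

    def test_minus_strand_nonsense(self, crafted_genome):
        # CDS codon 2 CAA→TAA read on the minus strand
        pos0 = 529 - 3  # offset 3 into the minus CDS
        r = vrec(chrom="chrA", pos=pos0 + 1, ref="G", alt="A")
        csq = ev.annotate_consequence(r, crafted_genome)
        assert csq.csq_class == "nonsense"
        assert csq.protein_notation == "Q2*"
        assert csq.gene_id == "minus_gene"

    def test_homopolymer_insertion_is_frameshift(self, crafted_genome):
        base = crafted_genome.chromosomes["chrA"][100]
        r = vrec(chrom="chrA", pos=101, ref=base, alt=base + "T")
        csq = ev.annotate_consequence(r, crafted_genome)
        assert csq.csq_class == "frameshift"
        assert csq.protein_notation.endswith("fs")

    def test_inframe_deletion(self, crafted_genome):
        seq = crafted_genome.chromosomes["chrA"]
        r = vrec(chrom="chrA", pos=101, ref=seq[100:104], alt=seq[100])
        csq = ev.annotate_consequence(r, crafted_genome)
        assert csq.csq_class == "inframe-indel"

    def test_intergenic_is_noncoding(self, crafted_genome):
        csq = ev.annotate_consequence(vrec(chrom="chrA", pos=3, ref="A", alt="G"), crafted_genome)
        assert csq == ev.Consequence(None, "noncoding", None)

    def test_boundary_spanning_variant_rejected(self, crafted_genome):
        seq = crafted_genome.chromosomes["chrA"]
        r = vrec(chrom="chrA", pos=9, ref=seq[8:12], alt=seq[8])
        with pytest.raises(ValueError, match="boundary"):
            ev.annotate_consequence(r, crafted_genome)

    def test_reference_mismatch_detected(self, crafted_genome):
        r = vrec(chrom="chrA", pos=10 + 19 * 3 + 1, ref="T", alt="G")
        with pytest.raises(ValueError, match="mismatch"):
            ev.annotate_consequence(r, crafted_genome)


# ---------------------------------------------------------------------------
# tracks: AF, LOH, CNV


def site_track(afs, chrom="chr1", start=100, spacing=10):
    rows = [
        {"chrom": chrom, "start": start + i * spacing,
         "end": start + i * spacing + 1, "value": af}
        for i, af in enumerate(afs)
    ]
    return GenomeTrack(pd.DataFrame(rows))


class TestAlleleFrequency:
    def test_freebayes_fields(self):
        r = vrec(SAF=25, SAR=25, DP=100)
        assert r.allele_frequency() == pytest.approx(0.5)

    def test_dp4_fields(self):
        r = vrec(caller="lofreq", DP4=(0, 0, 30, 30), DP=60)
        assert r.allele_frequency() == pytest.approx(1.0)

    def test_track_sorted_and_exact(self, toy_genome):
        vs = ev.gen_variant_set(toy_genome, 200, het_fraction=0.9, seed=4)
        track = ev.allele_frequency_track(vs)
        assert len(track) == 200
        starts = track.df.groupby("chrom")["start"].apply(
            lambda s: bool((s.diff().dropna() > 0).all())
        )
        assert starts.all()
        # generator writes exact 0.5 / 1.0 strand counts
        assert set(np.round(track.values(), 10)) <= {0.5, 1.0}


class TestLoh:
    def test_all_heterozygous_no_segments(self):
        assert ev.call_loh_segments(site_track([0.5] * 20)) == []

    def test_ten_site_hom_run_detected_once(self):
        afs = [0.5] * 5 + [1.0] * 10 + [0.5] * 5
        segs = ev.call_loh_segments(site_track(afs), min_sites=6)
        assert len(segs) == 1
        (seg,) = segs
        assert seg.n_sites == 10
        assert seg.state == "hom-alt-run"
        assert seg.mean_af == pytest.approx(1.0)

    def test_min_sites_larger_than_any_run_is_empty(self):
        afs = [0.5] * 5 + [1.0] * 10 + [0.5] * 5
        assert ev.call_loh_segments(site_track(afs), min_sites=11) == []

    def test_intermediate_site_breaks_run(self):
        afs = [1.0] * 6 + [0.5] + [1.0] * 6
        segs = ev.call_loh_segments(site_track(afs), min_sites=6)
        assert len(segs) == 2

    def test_hom_ref_runs_called(self):
        segs = ev.call_loh_segments(site_track([0.02] * 8), min_sites=6)
        assert len(segs) == 1 and segs[0].state == "hom-ref-run"

    def test_segments_never_overlap_and_idempotent(self):
        rng = np.random.default_rng(9)
        afs = rng.choice([0.0, 0.5, 1.0], size=200, p=[0.2, 0.5, 0.3])
        track = site_track(list(afs))
        segs1 = ev.call_loh_segments(track, min_sites=3)
        segs2 = ev.call_loh_segments(track, min_sites=3)
        assert segs1 == segs2
        by_chrom = sorted(segs1, key=lambda s: s.start)
        for a, b in zip(by_chrom, by_chrom[1:]):
            assert a.end <= b.start


class TestCnv:
    def test_uniform_depth_gives_ratio_exactly_one(self, toy_genome):
        rows = [
            {"chrom": c, "start": s, "end": s + 1000, "value": 80}
            for c in toy_genome.chromosomes
            for s in range(0, 30000, 1000)
        ]
        ratios = ev.cnv_windows(GenomeTrack(pd.DataFrame(rows)))
        assert np.all(ratios.values() == 1.0)
        assert ev.flag_cnv(ratios) == []

    def test_normalized_mean_is_one_by_construction(self, toy_genome):
        depth = ev.gen_depth_track(toy_genome, mean_depth=100, seed=6)
        ratios = ev.cnv_windows(depth)
        assert np.mean(ratios.values()) == pytest.approx(1.0, abs=1e-12)

    def test_implanted_duplication_recovered(self):
        genome = ev.gen_toy_genome(2, 100000, 5, seed=2)
        depth = ev.gen_depth_track(
            genome, mean_depth=100,
            cnv_segments=[("chr1", 10000, 18000, 2.0)], seed=6,
        )
        segs = ev.flag_cnv(ev.cnv_windows(depth))
        assert len(segs) == 1
        (seg,) = segs
        assert seg.direction == "gain"
        assert seg.chrom == "chr1"
        assert abs(seg.start - 10000) <= 1000 and abs(seg.end - 18000) <= 1000
        assert seg.mean_ratio == pytest.approx(2.0, rel=0.1)

    def test_zero_mean_depth_rejected(self):
        track = GenomeTrack(pd.DataFrame(
            [{"chrom": "chr1", "start": 0, "end": 1000, "value": 0}]
        ))
        with pytest.raises(ValueError, match="mean depth"):
            ev.cnv_windows(track)


# ---------------------------------------------------------------------------
# VCF I/O & report


class TestVcfIO:
    def test_write_read_identity(self, toy_genome, tmp_path):
        vs = ev.gen_variant_set(toy_genome, 100, seed=11, n_indels=2)
        path = tmp_path / "v.vcf"
        contigs = {c: len(s) for c, s in toy_genome.chromosomes.items()}
        ev.write_vcf(vs, path, contigs=contigs)
        loaded = ev.read_vcf(path)
        assert loaded.sorted().records == vs.sorted().records

    def test_multiallelic_split(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t5\t.\tA\tC,G\t50\t.\tDP=90\tGT\t0/1\n"
        )
        vs = ev.read_vcf(path)
        assert len(vs) == 2
        assert {r.alt for r in vs} == {"C", "G"}
        assert all(r.info["DP"] == 90 for r in vs)

    def test_missing_field_loaded_as_absent_marker(self, tmp_path):
        path = tmp_path / "nodp.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            '##INFO=<ID=MQM,Number=1,Type=Float,Description="mq">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t5\t.\tA\tC\t50\t.\tMQM=44\tGT\t0/1\n"
        )
        (r,) = ev.read_vcf(path).records
        assert r.info["DP"] is None
        res = ev.filter_freebayes(r)
        assert not res.passed and "missing:DP" in res.reasons

    def test_filter_column_written(self, toy_genome, tmp_path):
        vs = ev.gen_variant_set(toy_genome, 50, pass_fraction=0.5, seed=3)
        results = ev.apply_filters(vs)
        path = tmp_path / "f.vcf"
        contigs = {c: len(s) for c, s in toy_genome.chromosomes.items()}
        ev.write_vcf(vs, path, contigs=contigs, filters=results)
        text = path.read_text()
        assert "PASS" in text
        n_pass_lines = sum(
            1 for line in text.splitlines()
            if not line.startswith("#") and line.split("\t")[6] == "PASS"
        )
        assert n_pass_lines == sum(r.passed for r in results.values())


class TestMutationReport:
    def test_hand_counted_fixture(self, crafted_genome):
        records = [
            vrec(chrom="chrA", pos=p, ref="A", alt="G") for p in (1, 2, 5, 600)
        ] + [
            vrec(chrom="chrA", pos=10 + 19 * 3 + 1, ref="C", alt="T"),  # Q20*
            vrec(chrom="chrA", pos=10 + 134 * 3 + 1, ref="G", alt="A"),  # G135S
            vrec(chrom="chrA", pos=13, ref="G", alt="T"),  # L1L synonymous
            vrec(chrom="chrA", pos=16, ref="G", alt="T"),  # L2L synonymous
            vrec(chrom="chrA", pos=19, ref="G", alt="T"),  # L3L synonymous
            vrec(chrom="chrA", pos=527, ref="G", alt="A", zygosity="hom"),  # Q2*
        ]
        report = ev.mutation_report(VariantSet(records), crafted_genome)
        assert report["total"] == 10
        assert report["noncoding"] == 4
        assert report["coding"] == 6
        assert report["consequence_counts"]["nonsense"] == 2
        assert report["consequence_counts"]["missense"] == 1
        assert report["consequence_counts"]["synonymous"] == 3
        assert report["n_hom"] == 1
        assert set(report["genes_mutated"]) == {"plus_gene", "minus_gene"}

    def test_empty_set_all_zero(self, crafted_genome):
        report = ev.mutation_report(VariantSet([]), crafted_genome)
        assert report["total"] == 0
        assert report["coding"] == 0 and report["noncoding"] == 0

    def test_partitions_conserve_total(self, toy_genome):
        vs = ev.gen_variant_set(toy_genome, 371, seed=5, n_indels=1)
        report = ev.mutation_report(vs, toy_genome)
        assert report["noncoding"] + report["coding"] == report["total"] == 372
        assert sum(report["consequence_counts"].values()) == report["coding"]
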