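"""Anchored CDR extraction, composition comparison, clonotype statistics."""

import numpy as np
import pandas as pd
import pytest

from sybodykit.assembly import revcomp
from sybodykit.design import expected_frequencies
from sybodykit.qc import (
    QCError,
    Rejection,
    clonotype_stats,
    default_anchors,
    discrepancy_report,
    extract_cdrs,
    observed_frequencies,
    read_pairs_from_fastq,
)
from sybodykit.simulate import sample_variants, simulate_reads


@pytest.fixture(scope="module")
def small_readset(s10, s10_template):
    variants = sample_variants(s10, 300, seed=21)
    reads = simulate_reads(variants, 600, error_rate=0.0, seed=22,
                           template=s10_template)
    return variants, reads


class TestExtraction:
    def test_error_free_round_trip(self, s10, small_readset):
        variants, reads = small_readset
        exs, rejects = extract_cdrs(reads, s10)
        assert not rejects
        by_read = {(e.read_id, e.region): e for e in exs}
        for i, src in enumerate(reads.source):
            v = variants[src]
            for region, mate in (("CDR1", "1"), ("CDR3", "2")):
                ex = by_read[(f"{reads.ids[i]}/{mate}", region)]
                span = s10.region(region)
                for pos in s10.randomized_positions:
                    if pos in span:
                        assert ex.residue_at(pos) == v.residues[pos]

    def test_extraction_is_strand_safe(self, s10, small_readset):
        _, reads = small_readset
        subset = [(f"r{i}", reads.read1[i]) for i in range(20)]
        flipped = [(rid, revcomp(seq)) for rid, seq in subset]
        a, _ = extract_cdrs(subset, s10)
        b, _ = extract_cdrs(flipped, s10)
        assert [(e.read_id, e.region, e.residues) for e in a] == \
            [(e.read_id, e.region, e.residues) for e in b]

    def test_anchor_mismatch_within_budget_accepted(self, s10, small_readset):
        _, reads = small_readset
        seq = reads.read1[0]
        anchors = default_anchors(s10)
        a = anchors.region("CDR1")
        off = seq.find(a.upstream)
        assert off >= 0
        mutated = list(seq)
        mutated[off + 2] = "A" if mutated[off + 2] != "A" else "C"
        exs, rejects = extract_cdrs([("m", "".join(mutated))], s10, anchors)
        assert len(exs) == 1
        assert exs[0].anchor_mismatches[0] == 1

    def test_random_sequence_is_anchor_miss(self, s10):
        rng = np.random.default_rng(5)
        junk = "".join(rng.choice(list("ACGT"), 150))
        exs, rejects = extract_cdrs([("junk", junk)], s10)
        assert exs == []
        assert rejects == [Rejection("junk", None, "anchor-miss")]

    def test_frame_stop_rejected(self, s10, small_readset):
        _, reads = small_readset
        seq = reads.read1[0]
        anchors = default_anchors(s10)
        a = anchors.region("CDR1")
        off = seq.find(a.upstream) + len(a.upstream)
        mutated = seq[:off] + "TAA" + seq[off + 3:]
        exs, rejects = extract_cdrs([("stop", mutated)], s10, anchors)
        assert any(r.reason == "frame-stop" for r in rejects)

    def test_low_quality_read_rejected_with_floor(self, s10, small_readset):
        _, reads = small_readset
        rec = [("q", reads.read1[0], "#" * 150)]   # Q2 everywhere
        exs, rejects = extract_cdrs(rec, s10, min_quality=20)
        assert exs == [] and rejects[0].reason == "low-quality"

    def test_fastq_files_round_trip(self, s10, small_readset, tmp_path):
        _, reads = small_readset
        p1, p2 = reads.write_fastq(tmp_path / "qc")
        exs, rejects = extract_cdrs(read_pairs_from_fastq(p1, p2), s10)
        assert len(exs) == 2 * len(reads)
        assert not rejects


class TestObservedFrequencies:
    def test_simple_half_half(self, s10, small_readset):
        _, reads = small_readset
        exs, _ = extract_cdrs(reads, s10)
        cdr1 = [e for e in exs if e.region == "CDR1"][:4]
        # force a 2/2 split at the first randomized position
        pos = 26
        base = cdr1[0]
        fake = []
        for i, aa in enumerate("FFII"):
            res = list(base.residues)
            res[pos - base.protein_start] = aa
            fake.append(type(base)(f"r{i}", "CDR1", "".join(res),
                                   base.protein_start, (0, 0)))
        table = observed_frequencies(fake, s10)
        row = table[(table.position == pos)]
        freqs = dict(zip(row.amino_acid, row.frequency))
        assert freqs["F"] == pytest.approx(0.5)
        assert freqs["I"] == pytest.approx(0.5)

    def test_single_extraction_gives_unit_frequencies(self, s10,
                                                      small_readset):
        _, reads = small_readset
        exs, _ = extract_cdrs(reads, s10)
        one = [e for e in exs if e.region == "CDR3"][:1]
        table = observed_frequencies(one, s10)
        assert (table["frequency"] == 1.0).all()

    def test_empty_input_errors(self, s10):
        with pytest.raises(QCError):
            observed_frequencies([], s10)

    def test_frequencies_sum_to_one_per_position(self, s10, small_readset):
        _, reads = small_readset
        exs, _ = extract_cdrs(reads, s10)
        table = observed_frequencies(exs, s10)
        sums = table.groupby("position")["frequency"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestDiscrepancy:
    def test_identical_tables_all_in_lowest_bin(self, s10):
        exp = expected_frequencies(s10)
        obs = exp.copy()
        obs["count"] = 100
        obs["designed"] = True
        report = discrepancy_report(obs, exp)
        assert (report.table["discrepancy_pct"] == 0).all()
        assert (report.table["bin"] == "<10%").all()

    def test_relative_percent_formula_and_bin_edge(self):
        exp = pd.DataFrame({
            "position": [1], "region": ["CDR1"], "amino_acid": ["A"],
            "frequency": [0.10],
        })
        obs = pd.DataFrame({
            "position": [1], "region": ["CDR1"], "amino_acid": ["A"],
            "frequency": [0.113], "count": [113], "designed": [True],
        })
        report = discrepancy_report(obs, exp)
        row = report.table.iloc[0]
        assert row["discrepancy_pct"] == pytest.approx(13.0)
        assert row["bin"] == "10-20%"

    def test_unobserved_composition_flagged_unrepresented(self, s10):
        exp = expected_frequencies(s10)
        obs = exp[exp.region.isin(["CDR1", "CDR3"])].copy()
        obs["count"] = 50
        obs["designed"] = True
        drop = (obs["position"] == 26) & (obs["amino_acid"] == "F")
        obs = obs[~drop]
        report = discrepancy_report(obs, exp)
        row = report.table[(report.table.position == 26)
                           & (report.table.amino_acid == "F")].iloc[0]
        assert not row["represented"]
        assert row["bin"] is None

    def test_bin_counts_sum_to_represented(self, s10, small_readset):
        _, reads = small_readset
        exs, _ = extract_cdrs(reads, s10)
        report = discrepancy_report(
            observed_frequencies(exs, s10), expected_frequencies(s10)
        )
        s = report.summary
        assert (
            s["bin_lt10"] + s["bin_10_20"] + s["bin_gt20"] == s["represented"]
        ).all()
        assert (s["represented"] + s["unrepresented"] == s["n_compositions"]).all()

    def test_low_bin_fraction_grows_with_depth(self, s10, s10_template):
        fracs = []
        for depth in (1_000, 10_000, 100_000):
            vs = sample_variants(s10, depth, seed=31)
            reads = simulate_reads(vs, depth, error_rate=0.0, seed=32,
                                   template=s10_template)
            exs, _ = extract_cdrs(reads, s10)
            rep = discrepancy_report(
                observed_frequencies(exs, s10), expected_frequencies(s10)
            )
            fracs.append(
                rep.table["bin"].eq("<10%").sum() / len(rep.table)
            )
        assert fracs[0] <= fracs[1] <= fracs[2]
        assert fracs[0] < fracs[2]

    def test_bias_factor_recovered_from_observed_ratio(self, s10,
                                                       s10_template):
        from sybodykit.simulate import BiasModel
        pos, aa, factor = 99, "A", 1.5
        bias = BiasModel(factors={(pos, aa): factor})
        vs = sample_variants(s10, 30_000, bias=bias, seed=41)
        reads = simulate_reads(vs, 30_000, error_rate=0.0, seed=42,
                               template=s10_template)
        exs, _ = extract_cdrs(reads, s10)
        obs = observed_frequencies(exs, s10)
        w = s10.composition_at(pos).weights[aa]
        got = float(obs[(obs.position == pos)
                        & (obs.amino_acid == aa)]["frequency"].iloc[0]) / w
        expected_ratio = factor / (1 + (factor - 1) * w)   # renormalization
        assert got == pytest.approx(expected_ratio, rel=0.10)


class TestClonotypes:
    def _fake(self, rid, region, residues):
        from sybodykit.qc import ExtractedCDR
        return ExtractedCDR(rid, region, residues, 0, (0, 0))

    def test_all_distinct_keys(self):
        exs = []
        for i in range(10):
            exs.append(self._fake(f"r{i}/1", "CDR1", f"AAAA{i % 10}"[:4] + "FT"))
            exs.append(self._fake(f"r{i}/2", "CDR3", f"GY{i}"))
        ct = clonotype_stats(exs)
        assert ct.total == 10
        assert ct.unique_fraction == 1.0

    def test_single_repeated_key(self):
        exs = []
        for i in range(10):
            exs.append(self._fake(f"r{i}/1", "CDR1", "AAFT"))
            exs.append(self._fake(f"r{i}/2", "CDR3", "GYW"))
        ct = clonotype_stats(exs)
        assert ct.total == 10
        assert ct.unique_fraction == pytest.approx(0.1)

    def test_unpaired_reads_are_dropped_and_counted(self):
        exs = [
            self._fake("a/1", "CDR1", "AAFT"),
            self._fake("b/1", "CDR1", "AVFT"),
            self._fake("b/2", "CDR3", "GYW"),
        ]
        ct = clonotype_stats(exs)
        assert ct.total == 1
        assert ct.dropped == 1

    def test_high_uniqueness_without_pcr_duplication(self, s10, s10_template):
        # each read a distinct molecule drawn from ~1e18 diversity
        vs = sample_variants(s10, 10_000, seed=51)
        reads = simulate_reads(vs, 10_000, seed=52, template=s10_template,
                               with_replacement=False)
        exs, _ = extract_cdrs(reads, s10)
        ct = clonotype_stats(exs)
        assert ct.total == 10_000
        assert ct.unique_fraction > 0.999
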