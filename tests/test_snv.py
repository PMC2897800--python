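import numpy as np
import pytest
from Bio.Seq import Seq

from conftest import make_aln
from parmap.models import CdsInterval, Consequence, ReferenceSet, SNVCandidate
from parmap.simulate import SimulationConfig, SnvSpec, run_simulation
from parmap.snv import annotate_consequence, build_pileup, call_snvs, pileup_columns, snv_pipeline


def pileup_from_reads(reference, reads):
    """reads: list of (start, bases)."""
    alns = [make_aln(start, start + len(bases), read_seq=bases) for start, bases in reads]
    return build_pileup(alns, reference)


class TestPileup:
    def test_counts_aligned_bases_only(self):
        ref = ReferenceSet({"t": "A" * 100})
        a = make_aln(10, 50, right=10, read_seq="C" * 50)
        piles = build_pileup([a], ref)
        assert piles["t"][1, 10:50].sum() == 40   # C counted over aligned span
        assert piles["t"][:, 50:60].sum() == 0    # clipped bases never counted

    def test_column_stream_covers_only_covered_positions(self):
        ref = ReferenceSet({"t": "A" * 100})
        piles = pileup_from_reads(ref, [(10, "CCC"), (11, "GGG")])
        cols = list(pileup_columns(piles))
        assert [c.pos for c in cols] == [10, 11, 12, 13]
        assert cols[1].depth == 2
        assert all(c.depth == sum(c.counts) for c in cols)


class TestCallSnvs:
    @pytest.mark.parametrize("depth", range(2, 11))
    def test_threshold_grid(self, depth):
        """A call is emitted iff depth >= 3 and alt/depth > 0.75 strictly."""
        ref = ReferenceSet({"t": "A" * 50})
        for alt_count in range(depth + 1):
            reads = [(10, "G")] * alt_count + [(10, "A")] * (depth - alt_count)
            piles = pileup_from_reads(ref, reads)
            calls = call_snvs(piles, ref)
            expected = depth >= 3 and alt_count / depth > 0.75
            assert bool(calls) is expected, (depth, alt_count)
            if calls:
                (c,) = calls
                assert (c.ref_base, c.alt_base, c.depth, c.alt_count) == ("A", "G", depth, alt_count)

    def test_three_of_four_exactly_75_percent_is_not_called(self):
        ref = ReferenceSet({"t": "A" * 50})
        piles = pileup_from_reads(ref, [(10, "G")] * 3 + [(10, "A")])
        assert call_snvs(piles, ref) == []

    def test_tied_alternates_yield_no_call(self):
        ref = ReferenceSet({"t": "A" * 50})
        piles = pileup_from_reads(ref, [(10, "G")] * 2 + [(10, "C")] * 2)
        assert call_snvs(piles, ref) == []

    def test_n_bases_count_in_depth_but_not_as_alternate(self):
        ref = ReferenceSet({"t": "A" * 50})
        # 3 G + 1 N: fraction 3/4 == 0.75, not strictly greater -> no call
        piles = pileup_from_reads(ref, [(10, "G")] * 3 + [(10, "N")])
        assert call_snvs(piles, ref) == []


def toy_gene(seed=0, n_codons=100, strand="+", start=30):
    """A 300 nt CDS embedded in a longer random reference."""
    rng = np.random.default_rng(seed)
    length = 3 * n_codons
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=start + length + 30))
    ref = ReferenceSet({"t": seq})
    cds = CdsInterval("t", start, start + length, strand, 0, "toy")
    return ref, cds


def oracle_consequence(ref, cds, pos, alt):
    """Independent full-CDS translation oracle."""
    seq = ref["t"][cds.start:cds.end]
    offset = pos - cds.start
    mutated = seq[:offset] + alt + seq[offset + 1:]
    if cds.strand == "-":
        seq = str(Seq(seq).reverse_complement())
        mutated = str(Seq(mutated).reverse_complement())
    aa_ref = str(Seq(seq).translate())
    aa_alt = str(Seq(mutated).translate())
    return Consequence.SYNONYMOUS if aa_ref == aa_alt else Consequence.NONSYNONYMOUS


class TestAnnotateConsequence:
    def _cand(self, pos, ref, alt):
        return SNVCandidate("S1", "t", pos, ref, alt, depth=10, alt_count=10)

    def test_known_synonymous_and_nonsynonymous_codon_changes(self):
        # codon CGA (Arg): CGA->CGG synonymous, CGA->CCA (Pro) not
        seq = "AAA" + "CGA" + "AAA"
        ref = ReferenceSet({"t": seq})
        cds = [CdsInterval("t", 0, 9, "+", 0, "g")]
        assert annotate_consequence(self._cand(5, "A", "G"), cds, ref) is Consequence.SYNONYMOUS
        assert annotate_consequence(self._cand(4, "G", "C"), cds, ref) is Consequence.NONSYNONYMOUS

    def test_position_outside_cds_is_noncoding(self):
        ref, cds = toy_gene()
        c = self._cand(5, ref["t"][5], "A" if ref["t"][5] != "A" else "C")
        assert annotate_consequence(c, [cds], ref) is Consequence.NONCODING

    def test_no_annotation_is_unknown(self):
        ref, _ = toy_gene()
        c = self._cand(50, ref["t"][50], "A" if ref["t"][50] != "A" else "C")
        assert annotate_consequence(c, None, ref) is Consequence.UNKNOWN

    def test_truncated_codon_is_unknown(self):
        ref, _ = toy_gene()
        cds = [CdsInterval("t", 30, 35, "+", 0, "g")]  # 5 nt: last codon incomplete
        pos = 33
        c = self._cand(pos, ref["t"][pos], "A" if ref["t"][pos] != "A" else "C")
        assert annotate_consequence(c, cds, ref) is Consequence.UNKNOWN

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_agrees_with_translation_oracle_over_full_gene(self, strand):
        """Exhaustive scan: every CDS position, all three alternates."""
        ref, cds = toy_gene(strand=strand)
        for pos in range(cds.start, cds.end):
            ref_base = ref["t"][pos]
            for alt in "ACGT":
                if alt == ref_base:
                    continue
                got = annotate_consequence(self._cand(pos, ref_base, alt), [cds], ref)
                assert got is oracle_consequence(ref, cds, pos, alt), (pos, alt)


class TestPipeline:
    def test_error_free_planted_snvs_called_exactly(self):
        cfg = SimulationConfig(
            seed=21, n_samples=2, error_rate=0.0, mean_depth=40.0,
            snvs=(SnvSpec(samples=(0,)), SnvSpec(samples=(0, 1))),
        )
        res = run_simulation(cfg)
        calls = snv_pipeline(res.alignments, res.reference)
        truth = {(v.pos, frozenset(v.samples)) for v in res.truth}
        got = {}
        for sample_idx, sample in enumerate(cfg.sample_ids()):
            for c in calls[sample]:
                got.setdefault(c.pos, set()).add(sample_idx)
                truth_at = [v for v in res.truth if v.pos == c.pos]
                assert truth_at and truth_at[0].sequence == c.alt_base
                assert c.alt_fraction == 1.0
        assert {(pos, frozenset(s)) for pos, s in got.items()} == truth

    def test_false_call_rate_bounded_by_binomial_tail(self):
        """At depth 42 with 1% error, a false call needs >= ceil(0.75*42)+1 = 32
        identical errors; the binomial tail bound makes any false call over
        1e5 sites effectively impossible."""
        from scipy.stats import binom

        rng = np.random.default_rng(77)
        depth, err, n_sites = 42, 0.01, 100_000
        # errors land on each of the 3 alternates with probability err/3
        counts = rng.multinomial(depth, [1 - err, err / 3, err / 3, err / 3], size=n_sites)
        alt_max = counts[:, 1:].max(axis=1)
        threshold = max(3, int(np.floor(0.75 * depth)) + 1)
        false_calls = int((alt_max >= threshold).sum())
        bound = n_sites * 3 * binom.sf(threshold - 1, depth, err / 3)
        assert false_calls <= 3 * bound

    def test_synonymous_planted_variant_excluded_with_nonsynonymous_only(self):
        # CDS = one repeated CGA codon gene; plant CGA->CGG (synonymous) by hand
        ref = ReferenceSet({"t": "CGA" * 30})
        cds = [CdsInterval("t", 0, 90, "+", 0, "g")]
        # reads all report G at pos 5 (third base of codon 2): CGA->CGG
        alns = [make_aln(0, 30, read_seq=("CGA" + "CGG" + "CGA" * 8)) for _ in range(10)]
        calls = snv_pipeline({"S1": alns}, ref, annotation=cds, nonsynonymous_only=True)
        assert calls["S1"] == []
        calls = snv_pipeline({"S1": alns}, ref, annotation=cds)
        assert len(calls["S1"]) == 1
        assert calls["S1"][0].consequence is Consequence.SYNONYMOUS
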