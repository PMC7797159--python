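import numpy as np
import pandas as pd
import pytest

from lncnet import identify
from lncnet.identify import (
    OUTCOME_ANNOTATED,
    OUTCOME_LNCRNA,
    OUTCOME_REMOVED,
    OUTCOME_TUCP,
    count_orfs,
    filter_cascade,
    classify_lncrna,
)
from lncnet.types import SequenceSet, Transcript

from conftest import make_expression


def _tx(tid, n_exons=2, length=300, code="u"):
    per = length // n_exons
    exons = []
    pos = 1000
    for i in range(n_exons):
        ln = per if i < n_exons - 1 else length - per * (n_exons - 1)
        exons.append((pos, pos + ln - 1))
        pos += ln + 500
    return Transcript(tid, f"g_{tid}", "chr1", "+", tuple(exons), code)


def _verdicts(ids, coding_ids=()):
    rows = {
        t: {
            c: ("coding" if t in coding_ids else "noncoding")
            for c in ("cpc", "pfam", "phylocsf", "cnci")
        }
        for t in ids
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "transcript_id"
    return df


def _expr(ids, value=5.0):
    return make_expression({t: [value] * 12 for t in ids})


class TestCascadeBoundaries:
    @pytest.mark.parametrize(
        "tx, fpkm, outcome, step",
        [
            (_tx("t", n_exons=1), 5.0, OUTCOME_REMOVED, "exon"),
            (_tx("t", length=200), 5.0, OUTCOME_REMOVED, "length"),  # strict > 200
            (_tx("t", length=201), 5.0, OUTCOME_LNCRNA, None),
            (_tx("t", code="="), 5.0, OUTCOME_REMOVED, "overlap"),
            (_tx("t"), 0.49, OUTCOME_REMOVED, "expression"),
            (_tx("t"), 0.5, OUTCOME_LNCRNA, None),  # FPKM rule inclusive
        ],
    )
    def test_single_transcript_routing(self, tx, fpkm, outcome, step):
        expr = _expr([tx.transcript_id], fpkm)
        lnc, tucp, rep = filter_cascade([tx], expr, _verdicts([tx.transcript_id]))
        assert rep.records[tx.transcript_id] == (outcome, step)

    def test_any_coding_verdict_gives_tucp(self):
        tx = _tx("t")
        lnc, tucp, rep = filter_cascade(
            [tx], _expr(["t"]), _verdicts(["t"], coding_ids=["t"])
        )
        assert rep.records["t"] == (OUTCOME_TUCP, None)
        assert [t.transcript_id for t in tucp] == ["t"]

    def test_annotated_lncrna_routed_at_overlap_step(self):
        tx = _tx("t", code="=")
        lnc, tucp, rep = filter_cascade(
            [tx], _expr(["t"]), _verdicts(["t"]), annotated_lncrna_ids={"t"}
        )
        assert rep.records["t"] == (OUTCOME_ANNOTATED, None)
        assert lnc[0].biotype == "lncRNA_annotated"

    def test_missing_verdict_row_names_transcript(self):
        tx = _tx("t")
        with pytest.raises(KeyError, match="'t'"):
            filter_cascade([tx], _expr(["t"]), _verdicts([]))


def test_cascade_partitions_input(small_bundle):
    lnc, tucp, rep = filter_cascade(
        small_bundle.annotation,
        small_bundle.expression,
        small_bundle.verdicts,
        small_bundle.annotated_lncrna_ids,
    )
    all_in = {t.transcript_id for t in small_bundle.annotation}
    assert set(rep.records) == all_in
    retained = {t.transcript_id for t in lnc} | {t.transcript_id for t in tucp}
    removed = {t for t, (o, _s) in rep.records.items() if o == OUTCOME_REMOVED}
    assert retained | removed == all_in
    assert retained & removed == set()


def test_structural_screens_are_order_free_predicates(small_bundle):
    """The exon/length/expression screens remove exactly the transcripts
    failing at least one of the three predicates, however the cascade
    attributes the removal."""
    lnc, tucp, rep = filter_cascade(
        small_bundle.annotation,
        small_bundle.expression,
        small_bundle.verdicts,
        small_bundle.annotated_lncrna_ids,
    )
    max_fpkm = small_bundle.expression.fpkm.max(axis=1)
    removed_structural = {
        t for t, (o, s) in rep.records.items()
        if o == OUTCOME_REMOVED and s in ("exon", "length", "expression")
    }
    fails_any = {
        t.transcript_id
        for t in small_bundle.annotation
        if t.class_code not in identify.OVERLAP_CLASS_CODES
        and (t.n_exons < 2 or t.length <= 200 or max_fpkm[t.transcript_id] < 0.5)
    }
    # structural removals before the overlap step also catch overlap-coded
    # transcripts failing exon/length; restrict to the comparable universe
    non_overlap = {
        t.transcript_id for t in small_bundle.annotation
        if t.class_code not in identify.OVERLAP_CLASS_CODES
    }
    assert removed_structural & non_overlap == fails_any


class TestClassify:
    def test_u_and_x_codes(self):
        mapping = classify_lncrna([_tx("a", code="u"), _tx("b", code="x")])
        assert mapping == {"a": "lincRNA", "b": "antisense"}

    def test_unexpected_code_lists_offenders(self):
        with pytest.raises(ValueError, match="bad_tx"):
            classify_lncrna([_tx("bad_tx", code="i")])

    def test_empty_input(self):
        assert classify_lncrna([]) == {}


def _orf_oracle(seq, min_codons=30):
    """Literal scan: every ATG with an in-frame stop >= min_codons away."""
    stops = {"TAA", "TAG", "TGA"}
    n = 0
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        for stop in range(start + 3, len(seq) - 2, 3):
            if seq[stop : stop + 3] in stops:
                if (stop - start) // 3 >= min_codons:
                    n += 1
                break
    return n


class TestOrfs:
    def test_no_atg_gives_zero(self):
        assert count_orfs("CCCCCCCGGGGGGTTTTAA") == 0

    def test_minimum_length_boundary(self):
        body = "GGC" * 29  # 29 stop-free codons after the start
        assert count_orfs("ATG" + body + "TAA", min_codons=30) == 1
        assert count_orfs("ATG" + "GGC" * 28 + "TAA", min_codons=30) == 0

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(11)
        nucs = np.array(list("ACGT"))
        for _ in range(100):
            seq = "".join(nucs[rng.integers(0, 4, int(rng.integers(50, 600)))])
            assert count_orfs(seq, min_codons=5) == _orf_oracle(seq, min_codons=5)


def test_characterize_reports_missing_sequence(small_bundle, caplog):
    lnc, tucp, _rep = filter_cascade(
        small_bundle.annotation,
        small_bundle.expression,
        small_bundle.verdicts,
        small_bundle.annotated_lncrna_ids,
    )
    seqs = SequenceSet()
    out = identify.characterize({"lncRNA": lnc[:3]}, seqs, small_bundle.expression)
    assert out["values"]["n_orfs"].isna().all()
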