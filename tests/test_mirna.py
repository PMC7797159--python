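import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lncnet.mirna import (
    find_occurrences,
    precursor_homology,
    predict_targets,
    reverse_complement,
    seed_site,
)
from lncnet.types import MiRNA


MATURE = "TGAGGTAGTAGGTTGTATAGTT"  # 22 nt


class TestSeedMatching:
    def test_planted_site_found_with_position(self):
        site = seed_site(MATURE)  # revcomp of positions 2-8
        target = "A" * 40 + site + "C" * 40
        pairs = predict_targets([MiRNA("m1", MATURE)], {"t1": target}, "lncRNA")
        assert len(pairs) == 1
        assert pairs.iloc[0]["site_positions"] == [41]

    def test_no_site_no_pair(self):
        assert len(predict_targets([MiRNA("m1", MATURE)], {"t1": "A" * 100}, "mRNA")) == 0

    def test_short_mature_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            predict_targets([MiRNA("m1", "ACGTACG")], {"t": "ACGT" * 10}, "mRNA")

    def test_matches_sliding_window_scan(self):
        rng = np.random.default_rng(13)
        nucs = np.array(list("ACGT"))
        mirnas = [
            MiRNA(f"m{i}", "".join(nucs[rng.integers(0, 4, 22)])) for i in range(5)
        ]
        seqs = {
            f"t{i}": "".join(nucs[rng.integers(0, 4, int(rng.integers(60, 400)))])
            for i in range(100)
        }
        pairs = predict_targets(mirnas, seqs, "lncRNA")
        got = {
            (r.mirna_id, r.target_id): r.site_positions for r in pairs.itertuples()
        }
        for m in mirnas:
            site = seed_site(m.mature_seq)
            for tid, seq in seqs.items():
                expected = [
                    i + 1 for i in range(len(seq) - 6) if seq[i : i + 7] == site
                ]
                assert got.get((m.mirna_id, tid), []) == expected

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.text(alphabet="ACGU", min_size=22, max_size=22))
    def test_u_t_representation_invariant(self, mature_rna):
        mature_dna = mature_rna.replace("U", "T")
        target = "G" * 20 + seed_site(mature_dna) + "G" * 20
        target_rna = target.replace("T", "U")
        p1 = predict_targets([MiRNA("m", mature_rna)], {"t": target_rna}, "lncRNA")
        p2 = predict_targets([MiRNA("m", mature_dna)], {"t": target}, "lncRNA")
        assert p1.equals(p2) and len(p1) >= 1


class TestPrecursorHomology:
    def test_planted_66mer_at_309(self):
        rng = np.random.default_rng(4)
        nucs = np.array(list("ACGT"))
        pre = "".join(nucs[rng.integers(0, 4, 66)])
        host = "".join(nucs[rng.integers(0, 4, 500)])
        host = host[:308] + pre + host[308 + 66 :]
        hits = precursor_homology(
            {"lnc": host}, [MiRNA("mN1", MATURE, "mir-N1", pre)]
        )
        assert [(h.lncrna_id, h.precursor_id, h.start, h.end) for h in hits] == [
            ("lnc", "mir-N1", 309, 374)
        ]

    def test_absent_precursor_no_hit(self):
        hits = precursor_homology({"lnc": "ACGT" * 100}, [MiRNA("m", MATURE, "p", "TTTTT" * 12)])
        assert hits == []

    def test_double_planting_gives_two_hits(self):
        rng = np.random.default_rng(5)
        nucs = np.array(list("ACGT"))
        pre = "".join(nucs[rng.integers(0, 4, 60)])
        host = "".join(nucs[rng.integers(0, 4, 400)])
        host = host[:50] + pre + host[110:250] + pre + host[310:]
        hits = precursor_homology({"lnc": host}, [MiRNA("m", MATURE, "p", pre)])
        starts = [h.start for h in hits]
        # brute-force substring scan oracle
        assert starts == find_occurrences(host, pre)
        assert len(starts) == 2

    def test_hits_verbatim_and_multiple_hosts(self, small_bundle):
        lnc_seqs = {
            t: small_bundle.sequences[t]
            for t, b in small_bundle.truth.biotypes.items()
            if b == "lncRNA_novel"
        }
        hits = precursor_homology(lnc_seqs, small_bundle.mirnas)
        pre_seq = {m.precursor_id: m.precursor_seq for m in small_bundle.mirnas if m.precursor_id}
        for h in hits:
            assert lnc_seqs[h.lncrna_id][h.start - 1 : h.end] == pre_seq[h.precursor_id]
        got = {(h.lncrna_id, h.precursor_id, h.start, h.end) for h in hits}
        assert got == {tuple(x) for x in small_bundle.truth.precursor_positions}
        # mir-N2 is planted into two hosts
        assert sum(1 for h in hits if h.precursor_id == "mir-N2") == 2

    def test_no_spurious_hit_in_random_background(self):
        rng = np.random.default_rng(17)
        nucs = np.array(list("ACGT"))
        background = "".join(nucs[rng.integers(0, 4, 100_000)])
        pre = "".join(nucs[rng.integers(0, 4, 66)])
        assert precursor_homology({"bg": background}, [MiRNA("m", MATURE, "p", pre)]) == []

    def test_reverse_complement_mode(self):
        pre = "ACGTAGGCTA" * 6
        host = "T" * 30 + reverse_complement(pre) + "T" * 30
        assert precursor_homology({"l": host}, [MiRNA("m", MATURE, "p", pre)]) == []
        hits = precursor_homology(
            {"l": host}, [MiRNA("m", MATURE, "p", pre)], search_reverse_complement=True
        )
        assert len(hits) == 1
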