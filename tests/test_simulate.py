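import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from lncnet.simulate import (
    SimulationConfig,
    generate_dataset,
    read_dataset,
    write_dataset,
)
from lncnet.targets import span_gap
from lncnet.types import COMPARISON_LABELS

from conftest import SMALL_CONFIG


def _tree_digest(d: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(d.rglob("*")):
        if p.is_file():
            h.update(p.relative_to(d).as_posix().encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def test_same_seed_byte_identical(tmp_path):
    cfg = dataclasses.replace(SMALL_CONFIG)
    for sub in ("a", "b"):
        write_dataset(generate_dataset(cfg), tmp_path / sub)
    assert _tree_digest(tmp_path / "a") == _tree_digest(tmp_path / "b")


def test_different_seed_differs(tmp_path):
    b1 = generate_dataset(dataclasses.replace(SMALL_CONFIG, seed=1))
    b2 = generate_dataset(dataclasses.replace(SMALL_CONFIG, seed=2))
    assert not b1.expression.fpkm.equals(b2.expression.fpkm)


def test_no_planted_signal_gives_empty_de_truth():
    cfg = dataclasses.replace(
        SMALL_CONFIG, de_fraction=0.0, planted_triads=0, trans_pair_count=0
    )
    b = generate_dataset(cfg)
    assert len(b.truth.de) == 0
    for g in COMPARISON_LABELS:
        assert b.truth.de_features(g) == set()


def test_planted_triads_consistent_with_target_truth(small_bundle):
    truth = small_bundle.truth
    assert len(truth.triads) == SMALL_CONFIG.planted_triads
    targets = {
        (r.mirna_id, r.target_id, r.target_kind)
        for r in truth.mirna_targets.itertuples()
    }
    for lnc, mir, mrna, group in truth.triads:
        assert (mir, lnc, "lncRNA") in targets
        assert (mir, mrna, "mRNA") in targets
        # all three members planted DE (ceRNA grade) in the triad's group
        assert lnc in truth.de_features(group, 1.0)
        assert mrna in truth.de_features(group, 1.0)
        assert mir in truth.de_features(group, 1.0)


def test_noiseless_group_ratios_match_planted_log2fc():
    cfg = dataclasses.replace(SMALL_CONFIG, fpkm_sigma=1e-9, trans_pair_count=0)
    b = generate_dataset(cfg)
    means = b.expression.stage_means()
    for row in b.truth.de.itertuples():
        if row.feature_id not in means.index:
            continue  # miRNA truth rows live in the miRNA matrix
        num, den = row.group.split("v")
        observed = np.log2(means.loc[row.feature_id, num] / means.loc[row.feature_id, den])
        assert observed == pytest.approx(row.log2fc, abs=1e-3)


def test_cis_pairs_at_exact_offsets(small_bundle):
    tx = {t.transcript_id: t for t in small_bundle.annotation}
    for lnc, gene, dist in small_bundle.truth.cis_pairs:
        assert tx[lnc].chrom == tx[gene].chrom
        assert span_gap(tx[lnc].span, tx[gene].span) == dist
    planted = {d for _l, _g, d in small_bundle.truth.cis_pairs}
    assert planted == set(SMALL_CONFIG.cis_pair_distances)


def test_structure_contrasts_mrna_vs_lncrna(default_bundle):
    """mRNAs are longer, more exon-rich and more expressed than lncRNAs."""
    tx = default_bundle.annotation
    bt = default_bundle.truth.biotypes
    mrna = [t for t in tx if bt[t.transcript_id] == "mRNA"]
    lnc = [t for t in tx if bt[t.transcript_id].startswith("lncRNA")]
    assert np.mean([t.length for t in mrna]) > np.mean([t.length for t in lnc])
    assert np.mean([t.n_exons for t in mrna]) > np.mean([t.n_exons for t in lnc])
    fpkm = default_bundle.expression.fpkm
    assert (
        fpkm.loc[[t.transcript_id for t in mrna]].mean().mean()
        > fpkm.loc[[t.transcript_id for t in lnc]].mean().mean()
    )


def test_precursors_embedded_verbatim(small_bundle):
    pre_seq = {m.precursor_id: m.precursor_seq for m in small_bundle.mirnas if m.precursor_id}
    for host, pid, start, end in small_bundle.truth.precursor_positions:
        assert small_bundle.sequences[host][start - 1 : end] == pre_seq[pid]


def test_infeasible_precursor_placement_rejected():
    with pytest.raises(ValueError, match="cannot fit"):
        dataclasses.replace(
            SMALL_CONFIG, planted_precursors=((6, 10_000, 66, "mir-N1"),)
        )


def test_write_read_round_trip(tmp_path, small_bundle):
    write_dataset(small_bundle, tmp_path / "ds")
    back = read_dataset(tmp_path / "ds")
    assert back.annotation == small_bundle.annotation
    assert dict(back.sequences) == dict(small_bundle.sequences)
    assert back.mirnas == small_bundle.mirnas
    np.testing.assert_allclose(
        back.expression.fpkm.to_numpy(), small_bundle.expression.fpkm.to_numpy(), atol=1e-6
    )
    pd.testing.assert_frame_equal(
        back.expression.counts, small_bundle.expression.counts, check_names=False
    )
    pd.testing.assert_frame_equal(back.verdicts, small_bundle.verdicts)
    assert back.annotated_lncrna_ids == small_bundle.annotated_lncrna_ids
    assert back.truth.biotypes == small_bundle.truth.biotypes
    assert back.truth.cis_pairs == small_bundle.truth.cis_pairs
    assert back.truth.trans_pairs == small_bundle.truth.trans_pairs
    assert back.truth.triads == small_bundle.truth.triads
    assert back.truth.precursor_positions == small_bundle.truth.precursor_positions
    pd.testing.assert_frame_equal(back.truth.mirna_targets, small_bundle.truth.mirna_targets)
    assert back.gene_sets == small_bundle.gene_sets
    pd.testing.assert_frame_equal(back.ppi, small_bundle.ppi)


def test_config_yaml_round_trip(tmp_path):
    p = tmp_path / "cfg.yaml"
    SMALL_CONFIG.to_yaml(p)
    assert SimulationConfig.from_yaml(p) == SMALL_CONFIG
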