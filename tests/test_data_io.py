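import numpy as np
import pytest

from crossdti import data_io
from crossdti.data_io import (
    CompoundRecord,
    DataFormatError,
    SyntheticSpec,
    generate_synthetic_dti,
    read_compound_table,
    read_decoy_directory,
    read_dti_table,
    write_dti_table,
)

TOY_ROWS = [
    ("c1", "CCO", "t1", "MKLVAAAW", 1),
    ("c2", "CCN", "t1", "MKLVAAAW", 1),
    ("c3", "CCC", "t2", "MWWKLAVA", 1),
    ("c1", "CCO", "t2", "MWWKLAVA", 0),
    ("c2", "CCN", "t2", "MWWKLAVA", 0),
]


def _write_toy_table(path, rows=TOY_ROWS, delim="\t"):
    header = delim.join(["compound_id", "smiles", "target_id", "sequence", "label"])
    lines = [header] + [delim.join(str(x) for x in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")


def test_read_dti_table_counts_and_dedup(tmp_path):
    f = tmp_path / "pairs.tsv"
    _write_toy_table(f)
    ds = read_dti_table(f)
    assert len(ds.pairs) == 5
    assert sum(p.label for p in ds.pairs) == 3
    assert set(ds.compounds) == {"c1", "c2", "c3"}
    assert set(ds.targets) == {"t1", "t2"}


def test_read_dti_table_csv_dialect(tmp_path):
    f = tmp_path / "pairs.csv"
    _write_toy_table(f, delim=",")
    assert len(read_dti_table(f).pairs) == 5


def test_read_dti_table_header_only(tmp_path):
    f = tmp_path / "empty.tsv"
    _write_toy_table(f, rows=[])
    ds = read_dti_table(f)
    assert ds.pairs == [] and ds.compounds == {}


def test_read_dti_table_missing_column(tmp_path):
    f = tmp_path / "bad.tsv"
    f.write_text("compound_id\tsmiles\ttarget_id\tlabel\nc1\tCCO\tt1\t1\n")
    with pytest.raises(DataFormatError, match="sequence"):
        read_dti_table(f)


def test_read_dti_table_bad_label_reports_line(tmp_path):
    f = tmp_path / "bad.tsv"
    _write_toy_table(f, rows=TOY_ROWS[:2] + [("c3", "CCC", "t2", "MWWKLAVA", "yes")])
    with pytest.raises(DataFormatError, match="line 4"):
        read_dti_table(f)


def test_round_trip_and_row_permutation(tmp_path):
    f = tmp_path / "pairs.tsv"
    _write_toy_table(f)
    ds = read_dti_table(f)
    out = tmp_path / "out.tsv"
    write_dti_table(ds, out)
    again = read_dti_table(out)
    assert [(p.compound_id, p.target_id, p.label, p.split) for p in again.pairs] == [
        (p.compound_id, p.target_id, p.label, p.split) for p in ds.pairs
    ]
    # permuting data rows must not change the record sets
    _write_toy_table(tmp_path / "perm.tsv", rows=TOY_ROWS[::-1])
    perm = read_dti_table(tmp_path / "perm.tsv")
    assert set(ds.compounds) == set(perm.compounds)
    assert sorted((p.compound_id, p.target_id, p.label) for p in ds.pairs) == sorted(
        (p.compound_id, p.target_id, p.label) for p in perm.pairs
    )


def _make_decoy_dir(root, n_targets=2, n_actives=3, n_decoys=10):
    for t in range(n_targets):
        d = root / f"target{t}"
        d.mkdir(parents=True)
        (d / "actives.ism").write_text(
            "".join(f"CCO a{t}_{i}\n" for i in range(n_actives))
        )
        (d / "decoys.ism").write_text(
            "".join(f"CCN d{t}_{i}\n" for i in range(n_decoys))
        )


def test_read_decoy_directory(tmp_path):
    _make_decoy_dir(tmp_path)
    sets = read_decoy_directory(tmp_path)
    assert len(sets) == 2
    assert all(len(s.actives) == 3 and len(s.decoys) == 10 for s in sets)


def test_decoy_directory_excludes_targets_without_decoys(tmp_path, caplog):
    _make_decoy_dir(tmp_path, n_targets=1)
    lonely = tmp_path / "lonely"
    lonely.mkdir()
    (lonely / "actives.ism").write_text("CCO a0\n")
    with caplog.at_level("WARNING"):
        sets = read_decoy_directory(tmp_path)
    assert [s.target_id for s in sets] == ["target0"]
    assert any("lonely" in r.message for r in caplog.records)


def test_read_compound_table_flags_invalid(tmp_path):
    f = tmp_path / "compounds.csv"
    f.write_text(
        "compound_id,name,smiles\n"
        "n1,alpha,CCO\n"
        "n2,beta,\n"
        "n3,gamma,c1ccccc1\n"
        "n4,delta,CCN\n"
    )
    recs = read_compound_table(f)
    assert len(recs) == 4
    assert sum(r.valid for r in recs) == 3
    assert not next(r for r in recs if r.compound_id == "n2").valid


def test_read_compound_table_duplicate_id(tmp_path):
    f = tmp_path / "dup.csv"
    f.write_text("compound_id,name,smiles\nn1,a,CCO\nn1,b,CCN\n")
    with pytest.raises(DataFormatError, match="n1"):
        read_compound_table(f)


def test_compound_record_invalid_smiles_flagged():
    rec = CompoundRecord(compound_id="x", smiles="not_a_smiles")
    assert not rec.valid


class TestSyntheticGenerator:
    def test_seeded_determinism(self):
        spec = SyntheticSpec(n_targets=6, n_compounds=20, seed=7)
        ds1, tr1 = generate_synthetic_dti(spec)
        ds2, tr2 = generate_synthetic_dti(spec)
        assert [(p.compound_id, p.target_id, p.label, p.split) for p in ds1.pairs] == [
            (p.compound_id, p.target_id, p.label, p.split) for p in ds2.pairs
        ]
        assert tr1.truth == tr2.truth
        assert {c: ds1.compounds[c].smiles for c in ds1.compounds} == {
            c: ds2.compounds[c].smiles for c in ds2.compounds
        }

    def test_noise_free_labels_equal_truth(self):
        ds, truth = generate_synthetic_dti(SyntheticSpec(n_targets=6, n_compounds=20, noise_rate=0.0, seed=1))
        for p in ds.pairs:
            assert p.label == truth.truth[f"{p.compound_id}|{p.target_id}"]

    def test_positive_fraction_near_positive_rate(self):
        spec = SyntheticSpec(n_targets=40, n_compounds=200, noise_rate=0.0, positive_rate=0.25, seed=2)
        ds, _ = generate_synthetic_dti(spec)
        frac = np.mean([p.label for p in ds.pairs])
        se = np.sqrt(0.25 * 0.75 / len(ds.pairs))
        assert abs(frac - 0.25) < 3 * se + 0.02  # motif sharing adds mild correlation

    def test_positive_compound_carries_target_fragment(self):
        ds, truth = generate_synthetic_dti(SyntheticSpec(n_targets=8, n_compounds=30, noise_rate=0.0, seed=3))
        for p in ds.pairs:
            if truth.truth[f"{p.compound_id}|{p.target_id}"] == 1:
                frag = truth.target_fragment[p.target_id]
                assert frag in ds.compounds[p.compound_id].smiles
                assert truth.compound_motif[p.compound_id] in ds.targets[p.target_id].sequence

    def test_split_fractions(self):
        ds, _ = generate_synthetic_dti(SyntheticSpec(n_targets=10, n_compounds=50, seed=4))
        n = len(ds.pairs)
        assert abs(len(ds.split("train")) / n - 0.70) < 0.01
        assert abs(len(ds.split("validation")) / n - 0.15) < 0.01
        assert abs(len(ds.split("test")) / n - 0.15) < 0.01

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SyntheticSpec(n_targets=0)
        with pytest.raises(ValueError):
            SyntheticSpec(noise_rate=0.6)
        with pytest.raises(ValueError):
            SyntheticSpec(positive_rate=0.0)

    def test_all_smiles_valid(self):
        ds, _ = generate_synthetic_dti(SyntheticSpec(n_targets=6, n_compounds=40, seed=9))
        assert all(c.valid for c in ds.compounds.values())
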