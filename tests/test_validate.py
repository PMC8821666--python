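import numpy as np
import pandas as pd
import pytest

from dialib.io import Peak
from dialib.search import SSMRecord, search_file
from dialib.similarity import ScoreSet
from dialib.validate import (CHARGE_COLUMNS, FEATURE_COLUMNS,
                             N_FEATURE_COLUMNS, N_NAMED_FEATURES,
                             QUALITY_COLUMNS, SCALAR_FEATURES,
                             ValidationResult, assemble_features,
                             feature_matrix, iterative_rescore,
                             peptide_qvalues, tdc_qvalues, write_pin)


def make_record(qid="q1", peptide="PEPTIDEK", dot=0.9, is_decoy=False,
                charge_state=2, quality="Q1", second=None, scan=1):
    if second is None:
        second = 0.5 * dot
    assert second <= dot
    scores = ScoreSet(dot=dot, libc_cosSim=min(1.0, dot + 0.05), xcorr=dot,
                      pcc=0.8, kt=0.5, hgt=3.0, dotBias=0.3,
                      deltaD=(dot - second) / dot if dot else 0.0,
                      penalty=0.0, fval=0.6 * dot)
    return SSMRecord(
        query_id=qid, scan_number=scan, peptide=peptide, charge=2,
        proteins=["P1"], is_decoy=is_decoy, scores=scores,
        second_best_dot=second, mass_difference=0.01,
        precursor_mz_difference=0.005, charge_state=charge_state,
        quality_level=quality, hits_num=3, hits_mean=0.4, hits_stdev=0.2,
        pval=0.05)


class TestFeatureAssembly:
    def test_one_hot_blocks(self):
        row = assemble_features(make_record(charge_state=2, quality="Q3"))
        charge_block = row[len(SCALAR_FEATURES):len(SCALAR_FEATURES) + 5]
        quality_block = row[-3:]
        assert list(charge_block) == [0, 1, 0, 0, 0]
        assert list(quality_block) == [0, 0, 1]

    def test_feature_census(self):
        """17 scalar features + 2 categoricals = 19 named features,
        one-hot expanded to 25 numeric columns."""
        assert len(SCALAR_FEATURES) == 17
        assert len(CHARGE_COLUMNS) == 5
        assert len(QUALITY_COLUMNS) == 3
        assert N_NAMED_FEATURES == 19
        assert N_FEATURE_COLUMNS == 25
        row = assemble_features(make_record())
        assert row.shape == (25,)
        assert np.isfinite(row).all()

    def test_charge_above_five_clamps(self):
        row = assemble_features(make_record(charge_state=7))
        assert list(row[len(SCALAR_FEATURES):len(SCALAR_FEATURES) + 5]) == \
            [0, 0, 0, 0, 1]

    def test_deterministic(self):
        a = assemble_features(make_record())
        b = assemble_features(make_record())
        assert np.array_equal(a, b)

    def test_frozen_column_order(self):
        """Golden check of the full 25-column layout."""
        assert FEATURE_COLUMNS == [
            "massDiff", "precursorMzDiff", "dot", "deltaD", "dotBias",
            "fval", "penalty", "secondScore", "xcorr", "libc_cosSim", "kt",
            "hgt", "pcc", "hits_num", "hits_mean", "hits_stdev", "pval",
            "charge1", "charge2", "charge3", "charge4", "charge5",
            "qualityQ1", "qualityQ2", "qualityQ3",
        ]


class TestWritePin:
    def test_layout_and_labels(self, tmp_path):
        records = [make_record("q1"), make_record("q2", peptide="DECOY_X",
                                                  is_decoy=True, dot=0.3)]
        path = tmp_path / "out.pin"
        write_pin(records, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 3
        header = lines[0].split("\t")
        assert len(header) == 3 + 25 + 2
        assert header[:3] == ["SpecId", "Label", "ScanNr"]
        assert header[-2:] == ["Peptide", "Proteins"]
        assert lines[1].split("\t")[1] == "1"
        assert lines[2].split("\t")[1] == "-1"
        assert lines[1].split("\t")[-2] == "-.PEPTIDEK.-"

    def test_round_trip_reader_contract(self, tmp_path):
        records = [make_record(f"q{i}", dot=0.5 + i / 100,
                               is_decoy=(i % 3 == 0)) for i in range(9)]
        path = tmp_path / "out.pin"
        write_pin(records, path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns[3:28]) == FEATURE_COLUMNS
        assert set(df["Label"]) == {1, -1}
        assert np.allclose(df["dot"],
                           [r.scores.dot for r in records], atol=1e-6)


class TestTDCQvalues:
    def test_small_enumerated_case(self):
        records = [make_record("t1", dot=3.0), make_record("t2", dot=2.0),
                   make_record("d1", dot=1.0, is_decoy=True)]
        res = tdc_qvalues(records)
        by_id = dict(zip([r.query_id for r in records], res.qvalues))
        assert by_id["t1"] == 0.0
        assert by_id["t2"] == 0.0
        assert by_id["d1"] == pytest.approx(0.5)

    def test_all_decoys_on_top_caps_at_one(self):
        records = [make_record("d1", dot=0.9, is_decoy=True),
                   make_record("d2", dot=0.8, is_decoy=True),
                   make_record("t1", dot=0.5), make_record("t2", dot=0.4)]
        res = tdc_qvalues(records)
        assert (res.qvalues <= 1.0).all()
        assert res.qvalues[2] == 1.0  # 2 decoys / 2 targets above t1... capped

    def test_duplicated_input_keeps_per_record_qvalues(self):
        records = [make_record("t1", dot=3.0), make_record("d1", dot=1.0,
                                                           is_decoy=True)]
        doubled = records + [make_record("t1b", dot=3.0),
                             make_record("d1b", dot=1.0, is_decoy=True)]
        r1 = tdc_qvalues(records)
        r2 = tdc_qvalues(doubled)
        assert r2.qvalues[0] == pytest.approx(r1.qvalues[0])
        assert r2.qvalues[1] == pytest.approx(r1.qvalues[1])

    def test_qvalues_monotone_in_score(self):
        rng = np.random.default_rng(6)
        records = [make_record(f"q{i}", dot=float(rng.uniform(0, 1)),
                               is_decoy=bool(rng.random() < 0.5))
                   for i in range(200)]
        res = tdc_qvalues(records)
        order = np.argsort(-res.scores)
        assert (np.diff(res.qvalues[order]) >= -1e-12).all()

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(16)
        records = [make_record(f"q{i}", dot=float(rng.uniform(0, 1)),
                               is_decoy=bool(rng.random() < 0.5))
                   for i in range(100)]
        res1 = tdc_qvalues(records)
        perm = rng.permutation(100)
        res2 = tdc_qvalues([records[i] for i in perm])
        assert np.allclose(res1.qvalues[perm], res2.qvalues)

    def test_no_decoys_raises_with_guidance(self):
        with pytest.raises(ValueError, match="target\\+decoy"):
            tdc_qvalues([make_record("t1")])

    def test_ties_share_a_qvalue(self):
        records = [make_record("t1", dot=2.0), make_record("t2", dot=2.0),
                   make_record("d1", dot=2.0, is_decoy=True),
                   make_record("d2", dot=1.0, is_decoy=True)]
        res = tdc_qvalues(records)
        assert res.qvalues[0] == res.qvalues[1] == res.qvalues[2]


class TestPeptideQvalues:
    def test_best_ssm_per_peptide(self):
        records = [make_record("q1", "PEPA", dot=0.9),
                   make_record("q2", "PEPA", dot=0.7),
                   make_record("q3", "PEPB", dot=0.6),
                   make_record("q4", "DECOY_PEPC", dot=0.5, is_decoy=True)]
        res = tdc_qvalues(records)
        tab = res.peptide_table
        assert len(tab) == 3
        assert tab.set_index("peptide").loc["PEPA", "score"] == \
            pytest.approx(0.9)

    def test_reduces_to_ssm_level_when_one_ssm_per_peptide(self):
        records = [make_record(f"q{i}", f"PEP{i}K", dot=0.3 + 0.1 * i,
                               is_decoy=(i == 0)) for i in range(5)]
        res = tdc_qvalues(records)
        tab = res.peptide_table.set_index("peptide")
        for r, q in zip(res.records, res.qvalues):
            assert tab.loc[r.peptide, "qvalue"] == pytest.approx(q)


class TestIterativeRescore:
    def _separable_records(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        records = []
        for i in range(n):
            records.append(make_record(
                f"t{i}", f"TPEP{i}K", dot=float(rng.uniform(0.7, 1.0))))
            records.append(make_record(
                f"d{i}", f"DECOY_DPEP{i}K", dot=float(rng.uniform(0.0, 0.3)),
                is_decoy=True))
        return records

    def test_perfect_separation_is_preserved(self):
        records = self._separable_records()
        res = iterative_rescore(records, seed=3)
        targets = ~np.array([r.is_decoy for r in res.records])
        assert (res.qvalues[targets] == 0).all()

    def test_deterministic_for_fixed_seed(self):
        records = self._separable_records(seed=1)
        r1 = iterative_rescore(records, seed=9)
        r2 = iterative_rescore(records, seed=9)
        assert np.array_equal(r1.scores, r2.scores)
        assert np.array_equal(r1.qvalues, r2.qvalues)

    def test_falls_back_on_small_input(self):
        records = [make_record("t1", dot=0.9),
                   make_record("d1", dot=0.2, is_decoy=True)]
        res = iterative_rescore(records, seed=0)
        assert np.allclose(res.scores, [0.9, 0.2])

    def test_rescoring_improves_on_noisy_benchmark(self, mixed_benchmark):
        """On the mixed benchmark, rescoring with all features accepts at
        least as many true matches as the plain dot-product TDC."""
        lib, queries, truth = mixed_benchmark
        records = search_file(queries, lib)
        base = tdc_qvalues(records)
        res = iterative_rescore(records, seed=5)
        assert res.n_accepted(0.01) >= base.n_accepted(0.01) - 2
        acc = [r for r, q in zip(records, res.qvalues)
               if q <= 0.01 and not r.is_decoy]
        false = sum(truth.mapping[r.query_id] != r.peptide for r in acc)
        assert false / max(1, len(acc)) <= 0.05
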