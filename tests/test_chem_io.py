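import numpy as np
import pytest

from synthprice import (
    MoleculeRecord,
    PricedDataset,
    RawCatalogEntry,
    normalize_price,
    parse_and_canonicalize,
    preprocess_catalog,
    split_dataset,
)
from synthprice.errors import (
    ConfigError,
    EmptyDatasetError,
    InvalidStructureError,
    UnitError,
)


class TestCanonicalization:
    @pytest.mark.parametrize(
        "a,b",
        [
            ("OCC", "CCO"),
            ("c1ccccc1", "C1=CC=CC=C1"),  # aromatic vs Kekulé benzene
            ("C(C)O", "CCO"),
        ],
    )
    def test_equivalent_spellings_map_to_one_canonical_form(self, a, b):
        assert parse_and_canonicalize(a).canonical_smiles == parse_and_canonicalize(b).canonical_smiles

    @pytest.mark.parametrize("bad", ["C1CC", "not_a_smiles", "", "C(C"])
    def test_broken_input_raises_typed_error(self, bad):
        with pytest.raises(InvalidStructureError):
            parse_and_canonicalize(bad)

    def test_error_carries_offending_string(self):
        with pytest.raises(InvalidStructureError) as err:
            parse_and_canonicalize("C1CC")
        assert err.value.smiles == "C1CC"

    @pytest.mark.parametrize("smi", ["CCO", "c1ccncc1", "CC(=O)Oc1ccccc1C(=O)O", "[Na+].[Cl-]"])
    def test_canonicalization_is_idempotent(self, smi):
        once = parse_and_canonicalize(smi).canonical_smiles
        assert parse_and_canonicalize(once).canonical_smiles == once

    def test_salt_smiles_are_kept_if_parsable(self):
        rec = parse_and_canonicalize("[Na+].[Cl-]")
        assert "." in rec.canonical_smiles


class TestPriceNormalization:
    @pytest.mark.parametrize(
        "price,unit,mw,expected",
        [
            (1.0, "per-gram", 100.0, 0.1),
            (5.0, "per-mmol", 123.0, 5.0),
            (2.5, "per-mg", 250.0, 625.0),
            (1000.0, "per-mol", 50.0, 1.0),
        ],
    )
    def test_unit_conversion(self, price, unit, mw, expected):
        assert normalize_price(price, unit, mw) == pytest.approx(expected)

    @pytest.mark.parametrize("unit", [None, "per-kg", "per-lb", ""])
    def test_unknown_unit_raises(self, unit):
        with pytest.raises(UnitError):
            normalize_price(1.0, unit, 100.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            normalize_price(-1.0, "per-mmol", 100.0)
        with pytest.raises(ValueError):
            normalize_price(1.0, "per-gram", -5.0)


class TestPreprocessCatalog:
    def test_worked_six_entry_fixture(self, worked_catalog):
        dataset, report = preprocess_catalog(worked_catalog, min_price=2.0)
        assert report.n_input == 6
        assert report.n_unparsable == 1
        assert report.n_bad_unit == 0
        assert report.n_duplicates == 1
        assert report.n_below_min_price == 1
        assert report.n_survivors == 3
        assert report.conserved()
        prices = {r.canonical_smiles: r.log_price for r in dataset.records}
        assert prices["CCO"] == pytest.approx(np.log(4.0))  # min over suppliers
        assert prices["CCN"] == pytest.approx(np.log(5.0))
        assert prices["c1ccccc1"] == pytest.approx(np.log(3.0))

    def test_clean_catalog_reports_all_zero_removals(self):
        entries = [
            RawCatalogEntry("CCO", 5.0, "per-mmol"),
            RawCatalogEntry("CCN", 7.0, "per-mmol"),
        ]
        _, report = preprocess_catalog(entries)
        assert (report.n_unparsable, report.n_bad_unit, report.n_duplicates,
                report.n_below_min_price) == (0, 0, 0, 0)
        assert report.n_survivors == 2

    def test_all_below_cutoff_raises_empty_dataset(self):
        entries = [RawCatalogEntry("CCO", 0.5, "per-mmol")]
        with pytest.raises(EmptyDatasetError):
            preprocess_catalog(entries)

    def test_dedup_keeps_global_minimum_across_units(self):
        # 1 USD/g at MW 200 -> 0.2 USD/mmol... below cutoff; use higher prices
        entries = [
            RawCatalogEntry("CCO", 46.0, "per-gram", mol_weight=46.0),  # 2.116 USD/mmol
            RawCatalogEntry("OCC", 3.0, "per-mmol"),
        ]
        dataset, report = preprocess_catalog(entries)
        assert report.n_duplicates == 1
        assert dataset.records[0].log_price == pytest.approx(np.log(46.0 * 46.0 / 1000.0))

    def test_missing_unit_dropped_and_counted(self):
        entries = [
            RawCatalogEntry("CCO", 5.0, None),
            RawCatalogEntry("CCN", 5.0, "per-mmol"),
        ]
        _, report = preprocess_catalog(entries)
        assert report.n_bad_unit == 1
        assert report.conserved()

    def test_conservation_on_randomized_catalogs(self):
        rng = np.random.default_rng(4)
        pool = ["CCO", "CCN", "CCC", "bad(", "c1ccccc1", "CC(C)O", "C1CC"]
        units = ["per-mmol", "per-gram", None, "per-mg"]
        for _ in range(20):
            entries = [
                RawCatalogEntry(
                    pool[rng.integers(len(pool))],
                    float(rng.uniform(0.1, 50)),
                    units[rng.integers(len(units))],
                    mol_weight=float(rng.uniform(20, 300)),
                )
                for _ in range(rng.integers(3, 15))
            ]
            try:
                _, report = preprocess_catalog(entries)
            except EmptyDatasetError:
                continue
            assert report.conserved()

    def test_log_transform_preserves_price_ranking(self):
        entries = [
            RawCatalogEntry(s, p, "per-mmol")
            for s, p in [("CCO", 3.0), ("CCN", 30.0), ("CCC", 7.0), ("CCCC", 2.5)]
        ]
        dataset, _ = preprocess_catalog(entries)
        raw = {"CCO": 3.0, "CCN": 30.0, "CCC": 7.0, "CCCC": 2.5}
        recs = sorted(dataset.records, key=lambda r: r.log_price)
        assert [r.canonical_smiles for r in recs] == sorted(raw, key=raw.get)


class TestSplit:
    def _dataset(self, n):
        recs = [MoleculeRecord(f"{'C' * (i + 1)}", 1.0, i + 1, "ES") for i in range(n)]
        return PricedDataset(records=recs)

    def test_exact_fraction_sizes(self):
        ds = split_dataset(self._dataset(100), (0.9, 0.05, 0.05), seed=7)
        sizes = {s: sum(v == s for v in ds.split_assignment.values()) for s in ("train", "val", "test")}
        assert sizes == {"train": 90, "val": 5, "test": 5}

    def test_deterministic_under_seed(self):
        a = split_dataset(self._dataset(50), seed=7).split_assignment
        b = split_dataset(self._dataset(50), seed=7).split_assignment
        assert a == b

    def test_every_record_assigned_once(self):
        ds = split_dataset(self._dataset(37), seed=1)
        assert set(ds.split_assignment) == {r.canonical_smiles for r in ds.records}

    def test_bad_fractions_raise(self):
        with pytest.raises(ConfigError):
            split_dataset(self._dataset(10), (0.5, 0.5, 0.5), seed=0)
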