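"""Table loading, validation, subsetting and posterior persistence."""

import numpy as np
import pandas as pd
import pytest

from dietmix import data_io
from dietmix.data_io import (
    CoefficientPriors,
    DataLoadError,
    dataset_from_arrays,
    load_dataset,
    read_posterior,
    subset_fas,
    write_posterior,
)


@pytest.fixture
def tables(tmp_path):
    """A minimal consistent set of CSV tables (2 species, 4 FAs, 2 SIs)."""
    rng = np.random.default_rng(0)

    def comp_rows(k, p):
        x = rng.random((k, p)) + 0.1
        return x / x.sum(1, keepdims=True)

    prey_fa = pd.DataFrame(comp_rows(6, 4), columns=["fa1", "fa2", "fa3", "fa4"])
    prey_fa.insert(0, "species", ["krill"] * 3 + ["herring"] * 3)
    prey_fa.to_csv(tmp_path / "prey_fa.csv", index=False)

    pred_fa = pd.DataFrame(comp_rows(2, 4), columns=["fa1", "fa2", "fa3", "fa4"])
    pred_fa.insert(0, "id", ["p1", "p2"])
    pred_fa.to_csv(tmp_path / "predator_fa.csv", index=False)

    prey_si = pd.DataFrame(
        rng.normal([-18, 12], 0.5, size=(4, 2)), columns=["d13C", "d15N"]
    )
    prey_si.insert(0, "species", ["krill", "krill", "herring", "herring"])
    prey_si.to_csv(tmp_path / "prey_si.csv", index=False)

    pred_si = pd.DataFrame(
        rng.normal([-17, 14], 0.5, size=(2, 2)), columns=["d13C", "d15N"]
    )
    pred_si.insert(0, "id", ["p1", "p2"])
    pred_si.to_csv(tmp_path / "predator_si.csv", index=False)

    frac = pd.DataFrame(
        [
            {"species": s, "isotope": iso, "mean": m, "sd": 0.2}
            for s in ("krill", "herring")
            for iso, m in (("d13C", 1.0), ("d15N", 3.4))
        ]
    )
    frac.to_csv(tmp_path / "fractionation.csv", index=False)
    return tmp_path


def config_for(base, **keys):
    return {"tables": {k: str(base / v) for k, v in keys.items()}}


class TestLoadDataset:
    def test_fa_only_leaves_si_empty(self, tables):
        ds = load_dataset(
            config_for(tables, prey_fa="prey_fa.csv", predator_fa="predator_fa.csv")
        )
        assert ds.prey.si is None
        assert ds.species == ["krill", "herring"]
        assert ds.fa_names == ["fa1", "fa2", "fa3", "fa4"]
        np.testing.assert_allclose(ds.prey.fa.sum(1), 1.0)

    def test_full_load_with_si(self, tables):
        ds = load_dataset(
            config_for(
                tables,
                prey_fa="prey_fa.csv",
                predator_fa="predator_fa.csv",
                prey_si="prey_si.csv",
                predator_si="predator_si.csv",
                fractionation="fractionation.csv",
            )
        )
        assert ds.prey.iso_names == ["d13C", "d15N"]
        assert ds.priors.frac_mean.shape == (2, 2)
        np.testing.assert_allclose(ds.priors.frac_mean[:, 1], 3.4)

    def test_single_sample_species_rejected(self, tables):
        df = pd.read_csv(tables / "prey_fa.csv")
        df.loc[df.index[-1], "species"] = "lonely"
        df.to_csv(tables / "prey_fa.csv", index=False)
        with pytest.raises(DataLoadError, match="lonely"):
            load_dataset(
                config_for(tables, prey_fa="prey_fa.csv", predator_fa="predator_fa.csv")
            )

    def test_shuffled_columns_get_canonical_order(self, tables):
        df = pd.read_csv(tables / "predator_fa.csv")
        df = df[["id", "fa3", "fa1", "fa4", "fa2"]]
        df.to_csv(tables / "predator_fa.csv", index=False)
        ds = load_dataset(
            config_for(tables, prey_fa="prey_fa.csv", predator_fa="predator_fa.csv")
        )
        assert ds.fa_names == ["fa1", "fa2", "fa3", "fa4"]
        np.testing.assert_allclose(
            ds.predators.fa[0, 0], df.loc[0, "fa1"], rtol=1e-6
        )

    def test_percent_scaled_input(self, tables):
        df = pd.read_csv(tables / "prey_fa.csv")
        df[["fa1", "fa2", "fa3", "fa4"]] *= 100.0
        df.to_csv(tables / "prey_fa.csv", index=False)
        ds = load_dataset(
            config_for(tables, prey_fa="prey_fa.csv", predator_fa="predator_fa.csv")
        )
        np.testing.assert_allclose(ds.prey.fa.sum(1), 1.0)

    def test_negative_proportion_names_location(self, tables):
        df = pd.read_csv(tables / "prey_fa.csv")
        df.loc[1, "fa2"] = -0.1
        df.to_csv(tables / "prey_fa.csv", index=False)
        with pytest.raises(DataLoadError, match="row 1.*fa2"):
            load_dataset(
                config_for(tables, prey_fa="prey_fa.csv", predator_fa="predator_fa.csv")
            )

    def test_missing_table_names_file(self, tables):
        with pytest.raises(DataLoadError, match="nope.csv"):
            load_dataset(
                config_for(tables, prey_fa="nope.csv", predator_fa="predator_fa.csv")
            )

    def test_unknown_covariate_id_rejected(self, tables):
        pd.DataFrame({"id": ["p1", "zz"], "length": [10.0, 12.0]}).to_csv(
            tables / "cov.csv", index=False
        )
        with pytest.raises(DataLoadError, match="zz"):
            load_dataset(
                config_for(
                    tables,
                    prey_fa="prey_fa.csv",
                    predator_fa="predator_fa.csv",
                    covariates="cov.csv",
                )
            )

    def test_loading_is_deterministic(self, tables):
        cfg = config_for(tables, prey_fa="prey_fa.csv", predator_fa="predator_fa.csv")
        assert load_dataset(cfg).fingerprint() == load_dataset(cfg).fingerprint()

    def test_yaml_config_round_trip(self, tables):
        import yaml

        cfg = config_for(tables, prey_fa="prey_fa.csv", predator_fa="predator_fa.csv")
        cfg_path = tables / "run.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        ds = load_dataset(cfg_path)
        assert ds.species == ["krill", "herring"]


class TestSubsetFas:
    @pytest.fixture
    def ds(self, tables):
        return load_dataset(
            config_for(tables, prey_fa="prey_fa.csv", predator_fa="predator_fa.csv")
        )

    def test_subset_to_all_is_identity_up_to_closure(self, ds):
        sub = subset_fas(ds, ds.fa_names)
        np.testing.assert_allclose(sub.prey.fa, ds.prey.fa, atol=1e-12)

    def test_closure_arithmetic(self):
        ds = dataset_from_arrays(
            species=["a", "b"],
            fa_names=["f1", "f2", "f3", "f4"],
            prey_fa=np.array([[0.1, 0.2, 0.3, 0.4]] * 4),
            prey_fa_species=["a", "a", "b", "b"],
            predator_fa=np.array([[0.1, 0.2, 0.3, 0.4]]),
        )
        sub = subset_fas(ds, ["f1", "f2"])
        np.testing.assert_allclose(sub.prey.fa[0], [1 / 3, 2 / 3])

    def test_repeated_subset_equals_single(self, ds):
        once = subset_fas(ds, ["fa1", "fa2", "fa3"])
        twice = subset_fas(once, ["fa1", "fa2"])
        direct = subset_fas(ds, ["fa1", "fa2"])
        np.testing.assert_allclose(twice.prey.fa, direct.prey.fa, atol=1e-12)

    def test_unknown_name_rejected(self, ds):
        with pytest.raises(DataLoadError, match="fa9"):
            subset_fas(ds, ["fa1", "fa9"])

    def test_provenance_updated(self, ds):
        sub = subset_fas(ds, ["fa1", "fa2"])
        assert sub.provenance["fa_subset"] == ["fa1", "fa2"]


class TestPosteriorRoundTrip:
    @pytest.fixture
    def draws(self):
        from dietmix.sampler import PosteriorDraws

        rng = np.random.default_rng(7)
        return PosteriorDraws(
            draws=rng.normal(size=(2, 50, 3)),
            names=["pi[a]", "pi[b]", "Sigma_tau[0,0]"],
            seed=1,
            acceptance={},
            meta={"species": ["a", "b"]},
        )

    def test_round_trip_exact(self, tmp_path, draws):
        path, _ = write_posterior(draws, tmp_path / "draws.csv")
        back = read_posterior(path)
        np.testing.assert_array_equal(back.draws, draws.draws)
        assert back.names == draws.names

    def test_summary_has_one_row_per_parameter(self, tmp_path, draws):
        _, summary_path = write_posterior(draws, tmp_path / "draws.csv")
        summ = pd.read_csv(summary_path)
        assert len(summ) == len(draws.names)

    def test_empty_draws_rejected(self, tmp_path, draws):
        draws.draws = np.empty((2, 0, 3))
        with pytest.raises(ValueError):
            write_posterior(draws, tmp_path / "draws.csv")


def test_priors_defaults_are_fixed_no_conversion():
    pri = CoefficientPriors.defaults(3, 5)
    assert (pri.kappa_mean == 1).all() and (pri.kappa_var == 0).all()
    assert (pri.fat_mean == 1).all() and (pri.fat_var == 0).all()
    assert pri.frac_mean is None
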