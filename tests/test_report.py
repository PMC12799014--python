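import json

import numpy as np
import pandas as pd
import pytest

import stockdemog as sd


class TestDecadeSummary:
    def test_constant_decade(self):
        df = pd.DataFrame({
            "stock_id": "A",
            "year": np.arange(1990, 2000),
            "lambda_real": 1.0,
            "lambda_dem": 1.0,
            "prop": 1.0,
        })
        out = sd.decade_summary(df)
        assert list(out["decade"]) == [1990]
        assert out.loc[0, "lambda_real_median"] == 1.0
        assert out.loc[0, "lambda_real_mean"] == 1.0
        assert out.loc[0, "lambda_real_sd"] == pytest.approx(0.0)

    def test_median_of_log_rates_not_log_of_median(self):
        """r summaries are medians of ln(lambda): for rates {0.5, 2} the
        median lambda is 1.25 but the median r is 0."""
        df = pd.DataFrame({
            "stock_id": "A",
            "year": [1991, 1992],
            "lambda_real": [0.5, 2.0],
            "lambda_dem": [0.5, 2.0],
            "prop": [0.5, 1.0],
        })
        out = sd.decade_summary(df)
        assert out.loc[0, "lambda_real_median"] == pytest.approx(1.25)
        assert out.loc[0, "r_real_median"] == pytest.approx(0.0, abs=1e-12)

    def test_decade_binning_and_stock_counts(self):
        df = pd.DataFrame({
            "stock_id": ["A"] * 11 + ["B"] * 6,
            "year": list(range(1995, 2006)) + list(range(2000, 2006)),
            "lambda_real": 1.0,
            "lambda_dem": 1.1,
            "prop": 0.8,
        })
        out = sd.decade_summary(df).set_index("decade")
        assert list(out.index) == [1990, 2000]
        assert out.loc[1990, "n_stocks"] == 1
        assert out.loc[2000, "n_stocks"] == 2

    def test_empty_input(self):
        assert sd.decade_summary(pd.DataFrame()).empty


class TestGroupVariability:
    @staticmethod
    def _frame(values_by_stock):
        rows = []
        for stock, vals in values_by_stock.items():
            rows.append(pd.DataFrame({
                "stock_id": stock,
                "year": np.arange(2000, 2000 + len(vals)),
                "lambda_dem": vals,
            }))
        return pd.concat(rows, ignore_index=True)

    def test_identical_stocks_have_zero_spread(self):
        vals = [1.0, 1.2, 0.9, 1.1]
        frame = self._frame({"A": vals, "B": vals})
        groups = pd.DataFrame({
            "stock_id": ["A", "B"], "species": "cod", "region": "east",
        })
        out = sd.group_variability(frame, groups)
        assert out.loc[0, "sd_across_stocks"] == pytest.approx(0.0)

    def test_alternating_series_sd(self):
        vals = [0.9, 1.1] * 50
        frame = self._frame({"A": vals})
        groups = pd.DataFrame({"stock_id": ["A"], "species": "cod", "region": "east"})
        out = sd.group_variability(frame, groups)
        assert out.loc[0, "mean_sd_lambda_dem"] == pytest.approx(0.1005, abs=2e-4)
        assert np.isnan(out.loc[0, "sd_across_stocks"])  # singleton group

    def test_empty_group_dropped(self):
        frame = self._frame({"A": [1.0, 1.1]})
        groups = pd.DataFrame({
            "stock_id": ["A", "GHOST"],
            "species": ["cod", "hake"],
            "region": ["east", "west"],
        })
        out = sd.group_variability(frame, groups)
        assert list(out["species"]) == ["cod"]


@pytest.fixture(scope="module")
def stock_csv(tmp_path_factory):
    path = tmp_path_factory.mktemp("data") / "stocks.csv"
    stocks = []
    for k in range(3):
        cfg = sd.default_config(seed=100 + k, n_years=25)
        cfg.stock_id = f"SYN-{k}"
        cfg.species = "cod-like" if k < 2 else "herring-like"
        cfg.region = "east"
        stocks.append(sd.generate_stock(cfg))
    sd.write_stock_table(stocks, path)
    return path


class TestPipeline:
    @staticmethod
    def _config(stock_csv, outdir):
        return sd.PipelineConfig(
            inputs=[stock_csv],
            outdir=str(outdir),
            recovery=sd.RecoveryConfig(n_sims=100, horizon=30),
            dd_k_global=6,
            dd_k_stock=4,
            seed=5,
        )

    def test_end_to_end_bundle(self, stock_csv, tmp_path):
        bundle = sd.run_pipeline(self._config(stock_csv, tmp_path / "out"))
        assert bundle["manifest"]["n_stocks"] == 3
        assert bundle["manifest"]["n_converged"] == bundle["manifest"]["n_years_total"]
        for name in (
            "lambda_series.csv", "cohorts.csv", "recovery_classes.csv",
            "decade_summary.csv", "group_variability.csv", "manifest.json",
        ):
            assert (tmp_path / "out" / name).exists()
        with open(tmp_path / "out" / "manifest.json") as fh:
            manifest = json.load(fh)
        assert manifest["stocks"] == ["SYN-0", "SYN-1", "SYN-2"]

    def test_rerun_is_byte_identical(self, stock_csv, tmp_path):
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        sd.run_pipeline(self._config(stock_csv, out1))
        sd.run_pipeline(self._config(stock_csv, out2))
        for name in ("lambda_series.csv", "cohorts.csv", "recovery_curves.csv"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_missing_input_fails_fast(self, tmp_path):
        cfg = sd.PipelineConfig(inputs=[tmp_path / "absent.csv"], outdir=str(tmp_path / "o"))
        with pytest.raises(FileNotFoundError):
            sd.run_pipeline(cfg)
        assert not (tmp_path / "o").exists()

    def test_invalid_row_reported_with_coordinates(self, stock_csv, tmp_path):
        df = pd.read_csv(stock_csv)
        df.loc[3, "catch_n"] = df.loc[3, "abundance_n"] * 2
        bad = tmp_path / "bad.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(sd.StockTableError, match="catch exceeds abundance"):
            sd.run_pipeline(self._config(bad, tmp_path / "o"))
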