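"""Loading, validation and persistence of diet-analysis tables.

Five kinds of comma-separated tables are understood, all with a header row:

* prey FA profiles: ``species`` column + one column per fatty acid;
* predator FA profiles: ``id`` column + one column per fatty acid;
* prey / predator SI signatures: ``species`` (or ``id``) + one column per
  isotope, in per-mil units;
* conversion-coefficient priors (long): ``species, fa, mean, var``;
* fat-content priors: ``species, mean, var``;
* fractionation priors (long): ``species, isotope, mean, sd``;
* optional predator covariates: ``id`` + covariate columns.

FA rows may be given as percentages (detected when row sums are ~100 and
rescaled, with a logged notice). Rows are re-closed, zeros replaced by
multiplicative replacement, and all tables are aligned to a single
canonical FA order taken from the prey table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .compositions import closure_mat, replace_zeros_mat

logger = logging.getLogger(__name__)


class DataLoadError(ValueError):
    """A table failed validation; the message names file/row/column."""


@dataclasses.dataclass
class PreyLibrary:
    """Per-species FA and/or SI samples for the candidate prey sources.

    FA and SI tables may cover different individuals: no row pairing
    between markers is required or assumed.
    """

    species: list[str]
    fa_names: list[str] = dataclasses.field(default_factory=list)
    iso_names: list[str] = dataclasses.field(default_factory=list)
    fa: np.ndarray | None = None  # (N_fa_samples, p) closed rows
    fa_species: np.ndarray | None = None  # (N_fa_samples,) labels
    si: np.ndarray | None = None  # (N_si_samples, n_iso)
    si_species: np.ndarray | None = None

    @property
    def n_species(self) -> int:
        return len(self.species)

    def fa_rows(self, species: str) -> np.ndarray:
        return self.fa[self.fa_species == species]

    def si_rows(self, species: str) -> np.ndarray:
        return self.si[self.si_species == species]


@dataclasses.dataclass
class PredatorSamples:
    """Predator FA and/or SI signatures plus optional covariates.

    The FA and SI tables may describe different (even disjoint) sets of
    predators; ids are tracked separately per marker.
    """

    fa_ids: list[str] = dataclasses.field(default_factory=list)
    fa: np.ndarray | None = None
    si_ids: list[str] = dataclasses.field(default_factory=list)
    si: np.ndarray | None = None
    covariates: pd.DataFrame | None = None  # indexed by predator id

    @property
    def ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for i in list(self.fa_ids) + list(self.si_ids):
            seen.setdefault(i, None)
        return list(seen)


@dataclasses.dataclass
class CoefficientPriors:
    """Moment parametrizations for conversion (kappa), fat content (Phi)
    and fractionation (gamma) priors.

    kappa is gamma-distributed and Phi log-normal around the given means
    and variances; a variance of zero pins the coefficient at its mean.
    gamma (per-mil) is normal with the given mean and SD. Fractionation
    priors have no default: SI models refuse to run without them.
    """

    kappa_mean: np.ndarray  # (n_species, p)
    kappa_var: np.ndarray
    fat_mean: np.ndarray  # (n_species,)
    fat_var: np.ndarray
    frac_mean: np.ndarray | None = None  # (n_species, n_iso)
    frac_sd: np.ndarray | None = None

    def validate(self, n_species: int, p: int, n_iso: int) -> None:
        if self.kappa_mean.shape != (n_species, p) or self.kappa_var.shape != (
            n_species,
            p,
        ):
            raise DataLoadError("kappa prior tables do not match species x FA layout")
        if np.any(self.kappa_mean <= 0) or np.any(self.kappa_var < 0):
            raise DataLoadError("kappa prior means must be > 0 and variances >= 0")
        if self.fat_mean.shape != (n_species,) or self.fat_var.shape != (n_species,):
            raise DataLoadError("fat prior tables do not match species layout")
        if np.any(self.fat_mean <= 0) or np.any(self.fat_var < 0):
            raise DataLoadError("fat prior means must be > 0 and variances >= 0")
        if self.frac_mean is not None:
            if self.frac_mean.shape != (n_species, n_iso) or self.frac_sd.shape != (
                n_species,
                n_iso,
            ):
                raise DataLoadError(
                    "fractionation priors do not match species x isotope layout"
                )
            if np.any(self.frac_sd < 0):
                raise DataLoadError("fractionation SDs must be >= 0")

    @classmethod
    def defaults(cls, n_species: int, p: int) -> "CoefficientPriors":
        """No-conversion baseline: kappa = 1 and Phi = 1, both fixed."""
        return cls(
            kappa_mean=np.ones((n_species, p)),
            kappa_var=np.zeros((n_species, p)),
            fat_mean=np.ones(n_species),
            fat_var=np.zeros(n_species),
        )


@dataclasses.dataclass
class DietDataset:
    """A validated bundle of prey library, predator samples and priors."""

    prey: PreyLibrary
    predators: PredatorSamples
    priors: CoefficientPriors
    provenance: dict = dataclasses.field(default_factory=dict)

    @property
    def fa_names(self) -> list[str]:
        return self.prey.fa_names

    @property
    def species(self) -> list[str]:
        return self.prey.species

    def fingerprint(self) -> str:
        """Deterministic hash of the in-memory dataset contents."""
        h = hashlib.sha256()
        for arr in (
            self.prey.fa,
            self.prey.si,
            self.predators.fa,
            self.predators.si,
            self.priors.kappa_mean,
            self.priors.kappa_var,
            self.priors.fat_mean,
            self.priors.fat_var,
            self.priors.frac_mean,
            self.priors.frac_sd,
        ):
            if arr is not None:
                h.update(np.ascontiguousarray(arr, dtype=float).tobytes())
        h.update(",".join(self.species).encode())
        h.update(",".join(self.fa_names).encode())
        h.update(",".join(self.prey.iso_names).encode())
        return h.hexdigest()


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataLoadError(f"table not found: {path}")
    try:
        return pd.read_csv(path)
    except Exception as exc:  # malformed file
        raise DataLoadError(f"could not parse {path}: {exc}") from exc


def _profile_matrix(
    df: pd.DataFrame, value_cols: Sequence[str], file: str
) -> np.ndarray:
    sub = df[list(value_cols)]
    bad = sub.columns[sub.isna().any()].tolist()
    if bad:
        raise DataLoadError(f"{file}: missing values in columns {bad}")
    x = sub.to_numpy(dtype=float)
    neg = np.argwhere(x < 0)
    if neg.size:
        r, c = neg[0]
        raise DataLoadError(
            f"{file}: negative proportion at row {r}, column {value_cols[c]}"
        )
    sums = x.sum(axis=1)
    if np.allclose(sums, 100.0, rtol=0.05):
        logger.info("%s: rows sum to ~100; interpreting as percentages", file)
        x = x / 100.0
        sums = x.sum(axis=1)
    off = np.abs(sums - 1.0)
    if np.any(off > 1e-3):
        r = int(np.argmax(off))
        raise DataLoadError(
            f"{file}: row {r} sums to {sums[r]:.4f}; not a profile of proportions"
        )
    if np.any(off > 1e-9):
        logger.warning("%s: re-closing rows with sums off by up to %.2g", file, off.max())
    return closure_mat(x)


def load_dataset(config: Mapping | str | Path) -> DietDataset:
    """Load and validate a :class:`DietDataset` from a run configuration.

    ``config`` is a mapping (or path to a YAML file) with a ``tables``
    block naming CSV paths (``prey_fa``, ``predator_fa``, ``prey_si``,
    ``predator_si``, ``conversion``, ``fat``, ``fractionation``,
    ``covariates``) and optional top-level keys ``zero_delta`` (float or
    ``"auto"``) and ``fa_subset`` (list of FA names).
    """
    if isinstance(config, (str, Path)):
        cfg_path = Path(config)
        if not cfg_path.exists():
            raise DataLoadError(f"config file not found: {cfg_path}")
        with open(cfg_path) as fh:
            config = yaml.safe_load(fh)
        base = cfg_path.parent
    else:
        base = Path(".")
    tables = dict(config.get("tables", {}))

    def path_of(key: str) -> Path | None:
        if key not in tables or tables[key] is None:
            return None
        p = Path(tables[key])
        return p if p.is_absolute() else base / p

    prey_fa_path = path_of("prey_fa")
    prey_si_path = path_of("prey_si")
    if prey_fa_path is None and prey_si_path is None:
        raise DataLoadError("config must name at least one prey table (prey_fa/prey_si)")

    zero_delta = config.get("zero_delta", "auto")
    species: list[str] = []
    fa_names: list[str] = []
    iso_names: list[str] = []
    prey = PreyLibrary(species=species)

    if prey_fa_path is not None:
        df = _read_csv(prey_fa_path)
        if "species" not in df.columns:
            raise DataLoadError(f"{prey_fa_path}: missing 'species' column")
        fa_names = [c for c in df.columns if c != "species"]
        if len(fa_names) < 2:
            raise DataLoadError(f"{prey_fa_path}: need >= 2 FA columns")
        labels = df["species"].astype(str).to_numpy()
        counts = pd.Series(labels).value_counts()
        low = counts[counts < 2]
        if not low.empty:
            raise DataLoadError(
                f"{prey_fa_path}: species {list(low.index)} have < 2 samples "
                "(each species present in a table needs >= 2)"
            )
        x = _profile_matrix(df, fa_names, str(prey_fa_path))
        delta = None if zero_delta == "auto" else float(zero_delta)
        x = replace_zeros_mat(x, delta)
        prey.fa = x
        prey.fa_species = labels
        prey.fa_names = fa_names
        species.extend(pd.unique(labels))

    if prey_si_path is not None:
        df = _read_csv(prey_si_path)
        if "species" not in df.columns:
            raise DataLoadError(f"{prey_si_path}: missing 'species' column")
        iso_names = [c for c in df.columns if c != "species"]
        labels = df["species"].astype(str).to_numpy()
        counts = pd.Series(labels).value_counts()
        low = counts[counts < 2]
        if not low.empty:
            raise DataLoadError(
                f"{prey_si_path}: species {list(low.index)} have < 2 samples"
            )
        prey.si = df[iso_names].to_numpy(dtype=float)
        prey.si_species = labels
        prey.iso_names = iso_names
        for s in pd.unique(labels):
            if s not in species:
                species.append(s)

    # predators ------------------------------------------------------------
    predators = PredatorSamples()
    pred_fa_path = path_of("predator_fa")
    if pred_fa_path is not None:
        if prey.fa is None:
            raise DataLoadError("predator_fa given without prey_fa")
        df = _read_csv(pred_fa_path)
        if "id" not in df.columns:
            raise DataLoadError(f"{pred_fa_path}: missing 'id' column")
        missing = [c for c in fa_names if c not in df.columns]
        if missing:
            raise DataLoadError(f"{pred_fa_path}: missing FA columns {missing}")
        extra = [c for c in df.columns if c not in fa_names and c != "id"]
        if extra:
            raise DataLoadError(f"{pred_fa_path}: unknown FA columns {extra}")
        x = _profile_matrix(df, fa_names, str(pred_fa_path))  # canonical order
        delta = None if zero_delta == "auto" else float(zero_delta)
        predators.fa = replace_zeros_mat(x, delta)
        predators.fa_ids = df["id"].astype(str).tolist()

    pred_si_path = path_of("predator_si")
    if pred_si_path is not None:
        if prey.si is None:
            raise DataLoadError("predator_si given without prey_si")
        df = _read_csv(pred_si_path)
        if "id" not in df.columns:
            raise DataLoadError(f"{pred_si_path}: missing 'id' column")
        missing = [c for c in iso_names if c not in df.columns]
        if missing:
            raise DataLoadError(f"{pred_si_path}: missing isotope columns {missing}")
        predators.si = df[iso_names].to_numpy(dtype=float)
        predators.si_ids = df["id"].astype(str).tolist()

    if predators.fa is None and predators.si is None:
        raise DataLoadError("need at least one predator table (predator_fa/predator_si)")

    cov_path = path_of("covariates")
    if cov_path is not None:
        df = _read_csv(cov_path)
        if "id" not in df.columns:
            raise DataLoadError(f"{cov_path}: missing 'id' column")
        df["id"] = df["id"].astype(str)
        df = df.set_index("id")
        unknown = [i for i in df.index if i not in predators.ids]
        if unknown:
            raise DataLoadError(f"{cov_path}: unknown predator ids {unknown}")
        uncovered = [i for i in predators.ids if i not in df.index]
        if uncovered:
            raise DataLoadError(f"{cov_path}: predators without covariates {uncovered}")
        predators.covariates = df

    # priors ---------------------------------------------------------------
    n, p = len(species), len(fa_names)
    priors = CoefficientPriors.defaults(n, max(p, 1))
    if p == 0:
        priors.kappa_mean = np.ones((n, 0))
        priors.kappa_var = np.zeros((n, 0))

    conv_path = path_of("conversion")
    if conv_path is not None:
        df = _read_csv(conv_path)
        need = {"species", "fa", "mean", "var"}
        if not need <= set(df.columns):
            raise DataLoadError(f"{conv_path}: needs columns {sorted(need)}")
        km = np.ones((n, p))
        kv = np.zeros((n, p))
        for _, row in df.iterrows():
            s, f = str(row["species"]), str(row["fa"])
            if s not in species:
                raise DataLoadError(f"{conv_path}: unknown species {s!r}")
            if f not in fa_names:
                raise DataLoadError(f"{conv_path}: unknown FA {f!r}")
            km[species.index(s), fa_names.index(f)] = float(row["mean"])
            kv[species.index(s), fa_names.index(f)] = float(row["var"])
        priors.kappa_mean, priors.kappa_var = km, kv

    fat_path = path_of("fat")
    if fat_path is not None:
        df = _read_csv(fat_path)
        need = {"species", "mean", "var"}
        if not need <= set(df.columns):
            raise DataLoadError(f"{fat_path}: needs columns {sorted(need)}")
        fm = np.ones(n)
        fv = np.zeros(n)
        for _, row in df.iterrows():
            s = str(row["species"])
            if s not in species:
                raise DataLoadError(f"{fat_path}: unknown species {s!r}")
            fm[species.index(s)] = float(row["mean"])
            fv[species.index(s)] = float(row["var"])
        priors.fat_mean, priors.fat_var = fm, fv

    frac_path = path_of("fractionation")
    if frac_path is not None:
        df = _read_csv(frac_path)
        need = {"species", "isotope", "mean", "sd"}
        if not need <= set(df.columns):
            raise DataLoadError(f"{frac_path}: needs columns {sorted(need)}")
        gm = np.zeros((n, len(iso_names)))
        gs = np.zeros((n, len(iso_names)))
        seen = np.zeros((n, len(iso_names)), dtype=bool)
        for _, row in df.iterrows():
            s, iso = str(row["species"]), str(row["isotope"])
            if s not in species:
                raise DataLoadError(f"{frac_path}: unknown species {s!r}")
            if iso not in iso_names:
                raise DataLoadError(f"{frac_path}: unknown isotope {iso!r}")
            gm[species.index(s), iso_names.index(iso)] = float(row["mean"])
            gs[species.index(s), iso_names.index(iso)] = float(row["sd"])
            seen[species.index(s), iso_names.index(iso)] = True
        if not seen.all():
            raise DataLoadError(f"{frac_path}: incomplete species x isotope coverage")
        priors.frac_mean, priors.frac_sd = gm, gs

    priors.validate(n, p if p else priors.kappa_mean.shape[1], len(iso_names))

    ds = DietDataset(
        prey=prey,
        predators=predators,
        priors=priors,
        provenance={
            "tables": {k: str(v) for k, v in tables.items() if v is not None},
            "zero_delta": zero_delta,
            "fa_subset": None,
            "alr_ref": config.get("alr_ref", -1),
        },
    )
    subset = config.get("fa_subset")
    if subset:
        ds = subset_fas(ds, list(subset))
    logger.info(
        "loaded dataset: %d species, %d FAs, %d isotopes, %d FA / %d SI predators",
        len(species),
        len(ds.fa_names),
        len(iso_names),
        len(predators.fa_ids),
        len(predators.si_ids),
    )
    return ds


def dataset_from_arrays(
    species: Sequence[str],
    fa_names: Sequence[str] | None = None,
    prey_fa: np.ndarray | None = None,
    prey_fa_species: Sequence[str] | None = None,
    predator_fa: np.ndarray | None = None,
    iso_names: Sequence[str] | None = None,
    prey_si: np.ndarray | None = None,
    prey_si_species: Sequence[str] | None = None,
    predator_si: np.ndarray | None = None,
    priors: CoefficientPriors | None = None,
    predator_fa_ids: Sequence[str] | None = None,
    predator_si_ids: Sequence[str] | None = None,
    covariates: pd.DataFrame | None = None,
) -> DietDataset:
    """Assemble a DietDataset from in-memory arrays (simulator, tests)."""
    species = [str(s) for s in species]
    prey = PreyLibrary(
        species=species,
        fa_names=list(fa_names) if fa_names is not None else [],
        iso_names=list(iso_names) if iso_names is not None else [],
        fa=None if prey_fa is None else closure_mat(prey_fa),
        fa_species=None if prey_fa_species is None else np.asarray(prey_fa_species, dtype=object),
        si=None if prey_si is None else np.asarray(prey_si, dtype=float),
        si_species=None if prey_si_species is None else np.asarray(prey_si_species, dtype=object),
    )
    preds = PredatorSamples(covariates=covariates)
    if predator_fa is not None:
        preds.fa = closure_mat(predator_fa)
        preds.fa_ids = (
            [str(i) for i in predator_fa_ids]
            if predator_fa_ids is not None
            else [f"pred{i}" for i in range(preds.fa.shape[0])]
        )
    if predator_si is not None:
        preds.si = np.asarray(predator_si, dtype=float)
        preds.si_ids = (
            [str(i) for i in predator_si_ids]
            if predator_si_ids is not None
            else [f"pred{i}" for i in range(preds.si.shape[0])]
        )
    if priors is None:
        priors = CoefficientPriors.defaults(len(species), len(prey.fa_names))
    priors.validate(len(species), len(prey.fa_names), len(prey.iso_names))
    return DietDataset(prey=prey, predators=preds, priors=priors, provenance={})


def subset_fas(d: DietDataset, fa_names: Sequence[str]) -> DietDataset:
    """Restrict all FA tables to ``fa_names`` and re-close row-wise.

    The conversion-coefficient prior tables are restricted consistently
    (kappa is scale-free, so no renormalization is needed).
    """
    fa_names = [str(f) for f in fa_names]
    unknown = [f for f in fa_names if f not in d.fa_names]
    if unknown:
        raise DataLoadError(f"unknown FA names {unknown}")
    if len(fa_names) < 2:
        raise DataLoadError("an FA subset needs >= 2 names")
    idx = [d.fa_names.index(f) for f in fa_names]

    prey = dataclasses.replace(
        d.prey,
        fa_names=fa_names,
        fa=None if d.prey.fa is None else closure_mat(d.prey.fa[:, idx]),
    )
    preds = dataclasses.replace(
        d.predators,
        fa=None if d.predators.fa is None else closure_mat(d.predators.fa[:, idx]),
    )
    priors = dataclasses.replace(
        d.priors,
        kappa_mean=d.priors.kappa_mean[:, idx],
        kappa_var=d.priors.kappa_var[:, idx],
    )
    prov = dict(d.provenance)
    prov["fa_subset"] = fa_names
    return DietDataset(prey=prey, predators=preds, priors=priors, provenance=prov)


# ---------------------------------------------------------------------------
# posterior persistence
# ---------------------------------------------------------------------------


def write_posterior(draws, path: str | Path) -> tuple[Path, Path]:
    """Write draws as a long table (chain, iteration, parameter, value)
    plus a one-row-per-parameter summary table next to it."""
    from .sampler import PosteriorDraws, summarize  # local import: no cycle

    if not isinstance(draws, PosteriorDraws):
        raise TypeError("write_posterior expects PosteriorDraws")
    if draws.draws.size == 0:
        raise ValueError("refusing to write empty draws")
    path = Path(path)
    n_chains, n_draws, k = draws.draws.shape
    chain = np.repeat(np.arange(n_chains), n_draws * k)
    iteration = np.tile(np.repeat(np.arange(n_draws), k), n_chains)
    parameter = np.tile(np.asarray(draws.names, dtype=object), n_chains * n_draws)
    long = pd.DataFrame(
        {
            "chain": chain,
            "iteration": iteration,
            "parameter": parameter,
            "value": draws.draws.reshape(-1),
        }
    )
    long.to_csv(path, index=False, float_format="%.17g")
    summary_path = path.with_name(path.stem + "_summary.csv")
    summarize(draws).to_csv(summary_path)
    return path, summary_path


def read_posterior(path: str | Path):
    """Round-trip reader for :func:`write_posterior` long tables."""
    from .sampler import PosteriorDraws

    df = pd.read_csv(path, float_precision="round_trip")
    names = list(pd.unique(df["parameter"]))
    n_chains = df["chain"].nunique()
    n_draws = df["iteration"].nunique()
    arr = df["value"].to_numpy(dtype=float).reshape(n_chains, n_draws, len(names))
    return PosteriorDraws(draws=arr, names=names, seed=None, acceptance={}, meta={})
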