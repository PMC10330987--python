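"""Plain-text file formats and run configuration.

Everything is tab-separated text: a pedigree table, per-trait phenotype
tables, and an animals × markers dosage matrix (codes 0/1/2, NA for a
missing call) with a marker-metadata sidecar carrying the chip-panel tag of
each marker.  At the scale this pipeline targets (hundreds of genotyped
animals, ~10⁴ markers) text keeps every intermediate human-readable and
diff-able; the dosage-matrix layout is the common "one row per animal"
text export of genotyping pipelines.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .animal_model import McmcConfig
from .errors import ConfigError, DataError
from .genotype_qc import GenotypeMatrix
from .pedigree import PedigreeTable
from .simulate import SimulationConfig, TrueValues

SEP = "\t"
NA = "NA"


# ---------------------------------------------------------------------- #
# pedigree
# ---------------------------------------------------------------------- #
def write_pedigree(pedigree: PedigreeTable, path) -> None:
    df = pedigree.df.copy()
    if "birth_date" in df.columns:
        df["birth_date"] = pd.to_datetime(df["birth_date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, sep=SEP, index=False, na_rep=NA)


def read_pedigree(path) -> PedigreeTable:
    """Read a delimited pedigree (animal, sire, dam [, herd, sex,
    birth_date, ...]); unknown parents coded 0 or NA."""
    df = pd.read_csv(path, sep=SEP, na_values=[NA])
    return PedigreeTable.from_frame(df)


# ---------------------------------------------------------------------- #
# phenotypes
# ---------------------------------------------------------------------- #
def write_phenotypes(records: pd.DataFrame, path) -> None:
    df = records.copy()
    if "birth_date" in df.columns:
        df["birth_date"] = pd.to_datetime(df["birth_date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, sep=SEP, index=False, na_rep=NA)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=SEP, na_values=[NA])
    if "birth_date" in df.columns:
        df["birth_date"] = pd.to_datetime(df["birth_date"])
    return df


# ---------------------------------------------------------------------- #
# genotypes
# ---------------------------------------------------------------------- #
def write_genotypes(g: GenotypeMatrix, path, sidecar_path=None) -> None:
    """Write raw calls as an animal × marker dosage matrix.

    Only unimputed matrices round-trip: entries must be 0, 1, 2 or
    missing.  The optional sidecar lists marker id and panel tag.
    """
    data = g.data
    observed = data[~np.isnan(data)]
    if observed.size and np.any(observed != np.round(observed)):
        raise DataError(
            "matrix holds imputed (non-integer) dosages; write raw calls instead"
        )
    frame = pd.DataFrame(data, columns=g.markers)
    frame.insert(0, "animal", g.ids)
    with pd.option_context("future.no_silent_downcasting", True):
        out = frame.set_index("animal").astype("Int64").reset_index()
    out.to_csv(path, sep=SEP, index=False, na_rep=NA)
    if sidecar_path is not None:
        panel = g.panel if g.panel is not None else np.full(g.n_markers, NA)
        pd.DataFrame({"marker": g.markers, "panel": panel}).to_csv(
            sidecar_path, sep=SEP, index=False
        )


def read_genotypes(path, sidecar_path=None) -> GenotypeMatrix:
    """Read a dosage matrix, validating every token is 0, 1, 2 or NA.

    A bad token raises a DataError naming the offending animal row and
    marker column.
    """
    raw = pd.read_csv(path, sep=SEP, dtype=str, keep_default_na=False)
    if raw.columns[0] != "animal":
        raise DataError("genotype matrix must start with an 'animal' column")
    markers = np.asarray(raw.columns[1:])
    ids = pd.to_numeric(raw["animal"], errors="raise").to_numpy(dtype=np.int64)
    data = np.full((len(ids), len(markers)), np.nan)
    for j, marker in enumerate(markers):
        col = raw[marker].to_numpy()
        for i, token in enumerate(col):
            if token == NA or token == "":
                continue
            if token not in ("0", "1", "2"):
                raise DataError(
                    f"invalid genotype token {token!r} for animal {ids[i]} "
                    f"at marker {marker!r}"
                )
            data[i, j] = float(token)
    panel = None
    if sidecar_path is not None:
        side = pd.read_csv(sidecar_path, sep=SEP)
        tag = dict(zip(side["marker"].astype(str), side["panel"].astype(str)))
        try:
            panel = np.asarray([tag[str(m)] for m in markers])
        except KeyError as exc:
            raise DataError(f"marker {exc.args[0]!r} missing from sidecar") from exc
    return GenotypeMatrix(ids=ids, markers=markers, data=data, panel=panel)


# ---------------------------------------------------------------------- #
# truth file for recovery tests
# ---------------------------------------------------------------------- #
def write_truth(true_values: TrueValues, path) -> None:
    tbv = true_values.true_breeding_values
    pd.DataFrame({"animal": tbv.index, "true_bv": tbv.to_numpy()}).to_csv(
        path, sep=SEP, index=False
    )


def read_truth(path) -> pd.Series:
    df = pd.read_csv(path, sep=SEP)
    return pd.Series(df["true_bv"].to_numpy(), index=df["animal"].to_numpy())


# ---------------------------------------------------------------------- #
# run configuration
# ---------------------------------------------------------------------- #
@dataclass
class CvConfig:
    n_partitions: int = 100
    test_fraction: float = 0.2
    mcmc: McmcConfig = field(
        default_factory=lambda: McmcConfig(n_iterations=5_000, burn_in=5_000, thin=5)
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError("test_fraction must be inside (0, 1)")
        if self.n_partitions < 0:
            raise ConfigError("n_partitions must be non-negative (0 skips validation)")


@dataclass
class RunConfig:
    """Everything one end-to-end run needs.

    Either ``simulate`` is set (synthetic inputs are generated and written
    to ``outdir``) or the three input paths point at existing files.
    """

    trait: str = "BW"
    methods: tuple[str, ...] = ("BLUP", "GBLUP", "ssGBLUP")
    seed: int = 0
    outdir: str = "ssgblup-run"
    simulate: SimulationConfig | None = None
    pedigree_path: str | None = None
    phenotype_path: str | None = None
    genotype_path: str | None = None
    genotype_sidecar_path: str | None = None
    genotyped_ids_path: str | None = None
    sd_multiplier: float = 3.0
    call_rate_threshold: float = 0.95
    maf_threshold: float = 0.04
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    cv: CvConfig = field(default_factory=CvConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.call_rate_threshold <= 1.0:
            raise ConfigError("call_rate_threshold must be in (0, 1]")
        if not 0.0 <= self.maf_threshold < 0.5:
            raise ConfigError("maf_threshold must be in [0, 0.5)")
        if self.sd_multiplier < 0:
            raise ConfigError("sd_multiplier must be non-negative")
        unknown = set(self.methods) - {"BLUP", "GBLUP", "ssGBLUP"}
        if unknown:
            raise ConfigError(f"unknown methods: {sorted(unknown)}")
        if self.simulate is None and (
            self.pedigree_path is None or self.phenotype_path is None
        ):
            raise ConfigError("either simulate or input paths must be given")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            for key in ("year_range", "founder_allele_freq_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            for key in ("per_panel_marker_split", "variance_components"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["simulate"] = SimulationConfig(**sim)
        if "mcmc" in raw:
            raw["mcmc"] = McmcConfig(**raw["mcmc"])
        if "cv" in raw:
            cv = dict(raw["cv"])
            if "mcmc" in cv:
                cv["mcmc"] = McmcConfig(**cv["mcmc"])
            raw["cv"] = CvConfig(**cv)
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)
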