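"""Readers/writers for matrices, link tables, gene sets and edge lists.

All tabular formats are plain TSV (UTF-8, ``.`` decimal); gene sets use the
standard GMT dialect.  Readers validate and reject malformed input rather
than coercing it.  Every source of randomness in the package is derived from
a single integer seed through :func:`substream`, which hashes stage names
into independent child streams.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import zlib
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError

logger = logging.getLogger("omicreg")

#: Recognised omic labels, in canonical order.
OMICS = ("methylation", "transcript", "mirna")

#: Evidence categories accepted in link tables.
EVIDENCE_KINDS = ("predicted", "validated")


def substream(seed: int, *tags) -> np.random.Generator:
    """Return an independent RNG for a named stage.

    The child stream is a deterministic function of ``seed`` and the
    CRC32-hashed ``tags``, so stages draw from non-overlapping streams and
    reruns are reproducible regardless of stage ordering.
    """
    entropy = [int(seed) & 0xFFFFFFFF]
    entropy.extend(zlib.crc32(str(t).encode("utf-8")) for t in tags)
    return np.random.default_rng(np.random.SeedSequence(entropy))


@contextmanager
def stage_timer(name: str) -> Iterator[None]:
    """Log wall-clock duration of a pipeline stage."""
    t0 = time.perf_counter()
    logger.info("stage %s: started", name)
    try:
        yield
    finally:
        logger.info("stage %s: finished in %.2fs", name, time.perf_counter() - t0)


# ---------------------------------------------------------------------------
# multi-omic dataset
# ---------------------------------------------------------------------------


@dataclass
class MultiOmicDataset:
    """Feature x sample numeric matrix with omic and phenotype labels.

    ``values`` is oriented features x samples.  ``target_genes`` flags the
    transcript rows modelled as responses; they remain ordinary rows of the
    matrix.
    """

    values: np.ndarray
    feature_ids: list[str]
    feature_omic: list[str]
    sample_ids: list[str]
    sample_phenotype: list[str]
    target_genes: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()
        self._feature_index = {f: i for i, f in enumerate(self.feature_ids)}

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        n_feat, n_samp = self.values.shape
        if len(self.feature_ids) != n_feat:
            raise DataError("feature_ids length does not match matrix rows")
        if len(self.sample_ids) != n_samp:
            raise DataError("sample_ids length does not match matrix columns")
        if len(self.feature_omic) != n_feat:
            raise DataError("feature_omic length does not match matrix rows")
        if len(self.sample_phenotype) != n_samp:
            raise DataError("sample_phenotype length does not match matrix columns")
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dupes):
                raise DataError(f"duplicate {name} id: {dupes[0]!r}")
        bad = sorted(set(self.feature_omic) - set(OMICS))
        if bad:
            raise DataError(f"unknown omic label(s): {bad}")
        if len(set(self.feature_omic)) < 2:
            raise DataError("dataset must contain at least 2 omics")
        if not np.isfinite(self.values).all():
            raise DataError("matrix contains missing or non-finite values")
        omic_of = dict(zip(self.feature_ids, self.feature_omic))
        for g in self.target_genes:
            if g not in omic_of:
                raise DataError(f"target gene {g!r} absent from matrix")
            if omic_of[g] != "transcript":
                raise DataError(f"target gene {g!r} is not a transcript feature")

    # -- accessors ----------------------------------------------------------

    @property
    def phenotypes(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.sample_phenotype:
            seen.setdefault(p)
        return list(seen)

    def feature_row(self, feature_id: str) -> int:
        try:
            return self._feature_index[feature_id]
        except KeyError:
            raise DataError(f"feature {feature_id!r} not in dataset") from None

    def omic_of(self, feature_id: str) -> str:
        return self.feature_omic[self.feature_row(feature_id)]

    def features_of(self, omic: str) -> list[str]:
        return [f for f, o in zip(self.feature_ids, self.feature_omic) if o == omic]

    def omic_mask(self, omic: str) -> np.ndarray:
        return np.array([o == omic for o in self.feature_omic])

    def samples_of(self, phenotype: str) -> np.ndarray:
        return np.flatnonzero(np.array(self.sample_phenotype) == phenotype)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


def read_multiomic(matrix_path: str | Path, annotation_path: str | Path) -> MultiOmicDataset:
    """Load a dataset from a matrix TSV plus an annotation TSV.

    The matrix has a header row of sample ids and a first column of feature
    ids.  The annotation file has columns ``kind``/``id``/``label`` where
    ``kind`` is ``feature`` (label = omic), ``sample`` (label = phenotype) or
    ``target`` (label ignored).
    """
    matrix_path, annotation_path = Path(matrix_path), Path(annotation_path)
    with open(matrix_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    dupes = pd.Index(sample_ids)[pd.Index(sample_ids).duplicated()]
    if len(dupes):
        raise DataError(f"duplicate sample id: {dupes[0]!r}")
    frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
    feature_ids = [str(f) for f in frame.index]
    dupes = frame.index[frame.index.duplicated()]
    if len(dupes):
        raise DataError(f"duplicate feature id: {dupes[0]!r}")
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str, keep_default_na=False)
    required = {"kind", "id", "label"}
    if not required.issubset(ann.columns):
        raise DataError(f"annotation file must have columns {sorted(required)}")
    omic_map = dict(zip(ann.loc[ann["kind"] == "feature", "id"], ann.loc[ann["kind"] == "feature", "label"]))
    pheno_map = dict(zip(ann.loc[ann["kind"] == "sample", "id"], ann.loc[ann["kind"] == "sample", "label"]))
    targets = list(ann.loc[ann["kind"] == "target", "id"])
    missing = [f for f in feature_ids if f not in omic_map]
    if missing:
        raise DataError(f"feature without omic label: {missing[0]!r}")
    missing = [s for s in sample_ids if s not in pheno_map]
    if missing:
        raise DataError(f"sample without phenotype label: {missing[0]!r}")
    if frame.isna().any().any():
        raise DataError("matrix contains missing values")
    return MultiOmicDataset(
        values=frame.to_numpy(dtype=float),
        feature_ids=feature_ids,
        feature_omic=[omic_map[f] for f in feature_ids],
        sample_ids=sample_ids,
        sample_phenotype=[pheno_map[s] for s in sample_ids],
        target_genes=targets,
    )


def write_multiomic(dataset: MultiOmicDataset, matrix_path: str | Path, annotation_path: str | Path) -> None:
    """Write the dataset in the format :func:`read_multiomic` accepts."""
    dataset.to_frame().to_csv(matrix_path, sep="\t")
    rows = (
        [("feature", f, o) for f, o in zip(dataset.feature_ids, dataset.feature_omic)]
        + [("sample", s, p) for s, p in zip(dataset.sample_ids, dataset.sample_phenotype)]
        + [("target", g, "") for g in dataset.target_genes]
    )
    pd.DataFrame(rows, columns=["kind", "id", "label"]).to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# known regulator->target link tables
# ---------------------------------------------------------------------------


@dataclass
class KnownLinkDB:
    """Reference table of reported regulator->target links."""

    records: pd.DataFrame  # columns: regulator, target, evidence, source

    def __post_init__(self) -> None:
        cols = ["regulator", "target", "evidence", "source"]
        if list(self.records.columns) != cols:
            self.records = self.records.loc[:, cols]
        bad = set(self.records["evidence"]) - set(EVIDENCE_KINDS)
        if bad:
            raise DataError(f"unknown evidence kind(s): {sorted(bad)}")
        dup = self.records.duplicated(subset=["regulator", "target", "source"])
        if dup.any():
            row = self.records[dup].iloc[0]
            raise DataError(
                "duplicate link record: "
                f"({row['regulator']}, {row['target']}, {row['source']})"
            )

    def __len__(self) -> int:
        return len(self.records)

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.records["regulator"], self.records["target"]))

    def regulators(self) -> set[str]:
        return set(self.records["regulator"])

    def targets_of(self, regulator: str) -> set[str]:
        hit = self.records["regulator"] == regulator
        return set(self.records.loc[hit, "target"])

    def regulators_of(self, target: str) -> set[str]:
        hit = self.records["target"] == target
        return set(self.records.loc[hit, "regulator"])


def read_links(path: str | Path) -> KnownLinkDB:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"regulator", "target", "evidence", "source"}
    if not required.issubset(frame.columns):
        raise DataError(f"link table must have columns {sorted(required)}")
    return KnownLinkDB(records=frame)


def write_links(db: KnownLinkDB, path: str | Path) -> None:
    db.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file into ``{set name: member id set}``.

    Members are de-duplicated per line; empty sets are dropped with a logged
    warning; a line with fewer than three fields is rejected with its line
    number.
    """
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"GMT line {lineno}: expected >=3 fields, got {len(fields)}")
            name = fields[0]
            members = {m for m in fields[2:] if m}
            if not members:
                logger.warning("GMT line %d: empty set %r dropped", lineno, name)
                continue
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, set[str]], path: str | Path, descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc] + sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

EDGE_COLUMNS = ["source", "target", "coefficient", "omic", "phenotype"]


def write_edge_list(network, path: str | Path) -> None:
    """Write a predictor network as a directed edge-list TSV.

    Coefficients are written with :func:`repr` precision so signs and values
    survive a round trip unchanged.
    """
    frame = network.edges.copy()
    frame["phenotype"] = network.phenotype
    frame.loc[:, EDGE_COLUMNS].to_csv(path, sep="\t", index=False, float_format=None)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    missing = set(EDGE_COLUMNS) - set(frame.columns)
    if missing:
        raise DataError(f"edge list missing columns {sorted(missing)}")
    return frame


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Hyper-parameters of the fitting and testing pipeline.

    Defaults follow the published analysis protocol; :meth:`test_profile`
    scales the cross-validation effort down for desk-scale runs.
    """

    alpha: float = 0.5
    lambda_min: float = 0.001
    lambda_max: float = 1000.0
    lambda_grid_size: int = 100
    cv_repeats: int = 100
    train_fraction: float = 0.8
    small_cohort_threshold: int = 100
    k_small: int = 3
    k_large: int = 5
    fold_change_threshold: float = 1.1
    fdr_alpha: float = 0.05
    seed: int = 0
    subsample_n: int | None = None
    normal_phenotype: str = "Normal"
    solver_tol: float = 1e-7
    cv_tol: float = 3e-3
    ks_method: str = "asymp"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.lambda_min < self.lambda_max:
            raise ConfigError("lambda_min must be < lambda_max")
        if self.lambda_min <= 0:
            raise ConfigError("lambda_min must be positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("train_fraction must be in (0, 1)")
        if self.k_small < 2 or self.k_large < 2:
            raise ConfigError("fold counts must be >= 2")
        if self.lambda_grid_size < 2:
            raise ConfigError("lambda_grid_size must be >= 2")
        if self.cv_repeats < 1:
            raise ConfigError("cv_repeats must be >= 1")
        if self.fold_change_threshold < 1.0:
            raise ConfigError("fold_change_threshold must be >= 1")
        if self.subsample_n is not None and self.subsample_n < self.k_small + 2:
            raise ConfigError("subsample_n too small to split and cross-validate")

    @classmethod
    def paper_profile(cls, **overrides) -> "RunConfig":
        return cls(**overrides)

    @classmethod
    def test_profile(cls, **overrides) -> "RunConfig":
        overrides.setdefault("cv_repeats", 20)
        overrides.setdefault("lambda_grid_size", 50)
        return cls(**overrides)

    def lambda_grid(self) -> np.ndarray:
        """Log-spaced shrinkage grid, descending (largest first)."""
        return np.geomspace(self.lambda_max, self.lambda_min, self.lambda_grid_size)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown RunConfig field(s): {sorted(unknown)}")
        try:
            return cls(**dict(data))
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

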