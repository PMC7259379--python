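"""Synthetic multi-omic data with planted sparse regulatory structure.

Each phenotype receives its own feature matrix drawn from equicorrelated
Gaussian blocks.  Target-gene expression rows are overwritten with sparse
linear combinations of a few planted features per omic plus a weak
contribution from a designated hub miRNA (one hub active in tumor
phenotypes, a different one in the normal phenotype) and Gaussian noise
calibrated to a requested population R-squared.  The generator also emits
known-link tables with a tunable true-positive fraction and GMT gene-set
collections with one "on-target" set per gene, and records everything it
planted in a :class:`GroundTruth` for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ConfigError, DataError
from .io import EVIDENCE_KINDS, KnownLinkDB, MultiOmicDataset, substream

import pandas as pd

TUMOR_HUB = "mir_hubT"
NORMAL_HUB = "mir_hubN"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic-data generator.

    ``n_samples`` mirrors the per-phenotype cohort sizes of the motivating
    study so that both cross-validation branches (k=3 for small cohorts,
    k=5 for large ones) are exercised by default.
    """

    n_samples: Mapping[str, int] = field(
        default_factory=lambda: {"Basal": 125, "Her2": 45, "LumA": 395, "LumB": 128, "Normal": 75}
    )
    m_cpg: int = 900
    m_tx: int = 700
    m_mirna: int = 400
    n_target_genes: int = 10
    k_planted: int | Mapping[str, int] = 5
    coef_min: float = 1.2
    coef_max: float = 1.8
    rho: float = 0.9
    block_size: int = 5
    plant_within_blocks: bool = True
    r_squared: float = 0.7
    hub_scale: float = 0.5
    hub_sd: float = 18.0
    hub_de_shift_sds: float = 2.0
    shared_fraction: float = 0.0
    db_true_positive_fraction: float = 1.0
    db_size: int | None = None
    ontarget_coverage: float = 0.9
    ontarget_set_size: int = 30
    n_background_sets: int = 50
    normal_phenotype: str = "Normal"
    logit_normal_methylation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_samples:
            raise ConfigError("n_samples must name at least one phenotype")
        if any(n < 4 for n in self.n_samples.values()):
            raise ConfigError("each phenotype needs at least 4 samples")
        if self.normal_phenotype not in self.n_samples:
            raise ConfigError(f"normal phenotype {self.normal_phenotype!r} not in n_samples")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigError("rho must be in [0, 1)")
        if not 0.0 < self.r_squared < 1.0:
            raise ConfigError("r_squared must be in (0, 1)")
        if self.n_target_genes < 1 or self.n_target_genes > self.m_tx:
            raise ConfigError("n_target_genes must be in [1, m_tx]")
        ks = self.k_by_omic
        if any(k < 0 for k in ks.values()) or sum(ks.values()) < 1:
            raise ConfigError("k_planted must be non-negative with at least one omic > 0")
        if set(ks) - {"methylation", "transcript", "mirna"}:
            raise ConfigError("k_planted keys must be omic labels")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ConfigError("shared_fraction must be in [0, 1]")
        if not 0.0 <= self.db_true_positive_fraction <= 1.0:
            raise ConfigError("db_true_positive_fraction must be in [0, 1]")
        if not 0.0 < self.coef_min <= self.coef_max:
            raise ConfigError("coefficient range must satisfy 0 < coef_min <= coef_max")
        if self.hub_scale < 0:
            raise ConfigError("hub_scale must be >= 0")
        if self.hub_sd <= 0:
            raise ConfigError("hub_sd must be > 0")
        n_phen = len(self.n_samples)
        sizes = {
            "methylation": self.m_cpg,
            "transcript": self.m_tx - self.n_target_genes,
            "mirna": self.m_mirna - 2,
        }
        for omic, avail in sizes.items():
            k = ks[omic]
            n_shared = round(self.shared_fraction * k)
            need = n_shared + n_phen * (k - n_shared)
            if self.plant_within_blocks:
                # chunks are padded to block boundaries
                bs = self.block_size
                need = (
                    math.ceil(n_shared / bs) * bs
                    + n_phen * math.ceil((k - n_shared) / bs) * bs
                )
            if need > avail:
                raise ConfigError(
                    f"k_planted={k} needs {need} distinct {omic} features, "
                    f"only {avail} available"
                )

    @property
    def k_by_omic(self) -> dict[str, int]:
        if isinstance(self.k_planted, Mapping):
            ks = {o: 0 for o in ("methylation", "transcript", "mirna")}
            ks.update(self.k_planted)
            return ks
        return {o: int(self.k_planted) for o in ("methylation", "transcript", "mirna")}

    @property
    def phenotype_order(self) -> list[str]:
        return list(self.n_samples)

    @property
    def tumor_phenotypes(self) -> list[str]:
        return [p for p in self.n_samples if p != self.normal_phenotype]


@dataclass
class GroundTruth:
    """Record of everything the generator planted."""

    planted_coefficients: dict[tuple[str, str], list[tuple[str, float]]]
    intercepts: dict[tuple[str, str], float]
    noise_sd: dict[tuple[str, str], float]
    tumor_hub_id: str
    normal_hub_id: str
    hub_coefficient_scale: float
    block_assignments: dict[str, int]
    feature_omic: dict[str, str]
    target_genes: list[str]
    normal_phenotype: str
    db_true_positive_fraction: float
    planted_function_sets: dict[str, str] = field(default_factory=dict)

    def planted_features(self, phenotype: str, gene: str) -> set[str]:
        return {f for f, _ in self.planted_coefficients[(phenotype, gene)]}

    def planted_pairs(self, include_hubs: bool = True) -> set[tuple[str, str]]:
        """All planted (regulator feature, target gene) pairs across phenotypes."""
        pairs: set[tuple[str, str]] = set()
        for (ph, gene), coefs in self.planted_coefficients.items():
            for fid, _ in coefs:
                if include_hubs or fid not in (self.tumor_hub_id, self.normal_hub_id):
                    pairs.add((fid, gene))
        return pairs

    def validate(self, dataset: MultiOmicDataset) -> None:
        measured = set(dataset.feature_ids)
        for (ph, gene), coefs in self.planted_coefficients.items():
            for fid, _ in coefs:
                if fid not in measured:
                    raise DataError(f"planted feature {fid!r} missing from dataset")
                if fid == gene:
                    raise DataError(f"gene {gene!r} planted as its own predictor")
        for hub in (self.tumor_hub_id, self.normal_hub_id):
            if dataset.omic_of(hub) != "mirna":
                raise DataError(f"hub {hub!r} is not a mirna feature")

    # -- JSON round trip ----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        coefs = {}
        for (ph, gene), lst in self.planted_coefficients.items():
            coefs.setdefault(ph, {})[gene] = [[f, c] for f, c in lst]
        payload = {
            "planted_coefficients": coefs,
            "intercepts": {f"{ph}\t{g}": v for (ph, g), v in self.intercepts.items()},
            "noise_sd": {f"{ph}\t{g}": v for (ph, g), v in self.noise_sd.items()},
            "tumor_hub_id": self.tumor_hub_id,
            "normal_hub_id": self.normal_hub_id,
            "hub_coefficient_scale": self.hub_coefficient_scale,
            "block_assignments": self.block_assignments,
            "feature_omic": self.feature_omic,
            "target_genes": self.target_genes,
            "normal_phenotype": self.normal_phenotype,
            "db_true_positive_fraction": self.db_true_positive_fraction,
            "planted_function_sets": self.planted_function_sets,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        planted = {
            (ph, gene): [(f, float(c)) for f, c in lst]
            for ph, genes in data["planted_coefficients"].items()
            for gene, lst in genes.items()
        }
        split = lambda k: tuple(k.split("\t"))
        return cls(
            planted_coefficients=planted,
            intercepts={split(k): float(v) for k, v in data["intercepts"].items()},
            noise_sd={split(k): float(v) for k, v in data["noise_sd"].items()},
            tumor_hub_id=data["tumor_hub_id"],
            normal_hub_id=data["normal_hub_id"],
            hub_coefficient_scale=float(data["hub_coefficient_scale"]),
            block_assignments={k: int(v) for k, v in data["block_assignments"].items()},
            feature_omic=data["feature_omic"],
            target_genes=list(data["target_genes"]),
            normal_phenotype=data["normal_phenotype"],
            db_true_positive_fraction=float(data["db_true_positive_fraction"]),
            planted_function_sets=dict(data["planted_function_sets"]),
        )


# ---------------------------------------------------------------------------
# feature bookkeeping
# ---------------------------------------------------------------------------


def _feature_ids(config: SimulationConfig):
    cpgs = [f"cpg_{i:05d}" for i in range(config.m_cpg)]
    targets = [f"tgt_{i:02d}" for i in range(config.n_target_genes)]
    txs = [f"tx_{i:05d}" for i in range(config.m_tx - config.n_target_genes)]
    mirs = [TUMOR_HUB, NORMAL_HUB] + [f"mir_{i:04d}" for i in range(config.m_mirna - 2)]
    feature_ids = cpgs + txs + targets + mirs
    feature_omic = (
        ["methylation"] * len(cpgs)
        + ["transcript"] * (len(txs) + len(targets))
        + ["mirna"] * len(mirs)
    )
    return feature_ids, feature_omic, targets


def _assign_blocks(config: SimulationConfig, feature_ids, feature_omic, targets) -> dict[str, int]:
    """Consecutive features of an omic share equicorrelated blocks.

    Hubs sit in singleton blocks; target rows carry block -1 because their
    content is replaced by generated responses.
    """
    blocks: dict[str, int] = {}
    next_block = 0
    target_set = set(targets)
    for omic in ("methylation", "transcript", "mirna"):
        members = [
            f
            for f, o in zip(feature_ids, feature_omic)
            if o == omic and f not in target_set and f not in (TUMOR_HUB, NORMAL_HUB)
        ]
        for i, fid in enumerate(members):
            if i % config.block_size == 0:
                next_block += 1
            blocks[fid] = next_block
    for hub in (TUMOR_HUB, NORMAL_HUB):
        next_block += 1
        blocks[hub] = next_block
    for t in targets:
        blocks[t] = -1
    return blocks


def _plant_sets(config: SimulationConfig, feature_ids, feature_omic, targets, blocks):
    """Planted predictors with coefficients per (phenotype, gene).

    Sets are disjoint across phenotypes up to the configured shared
    fraction.  In block mode each phenotype's chunk is drawn from fresh
    correlated blocks and carries one common coefficient sign, so planted
    features reinforce each other marginally (the correlated-group signal
    the elastic net is built to pick up); in flat mode features and signs
    are drawn independently.
    """
    target_set = set(targets)
    pools = {
        omic: [
            f
            for f, o in zip(feature_ids, feature_omic)
            if o == omic and f not in target_set and f not in (TUMOR_HUB, NORMAL_HUB)
        ]
        for omic in ("methylation", "transcript", "mirna")
    }
    planted: dict[tuple[str, str], list[tuple[str, float]]] = {
        (ph, g): [] for ph in config.phenotype_order for g in targets
    }
    bs = config.block_size

    # In block mode, hand whole blocks to genes from one global permutation
    # per omic: when capacity allows, no two genes plant in the same block,
    # reproducing the near-total predictor exclusivity seen downstream.
    global_order: dict[str, list[str]] = {}
    offsets: dict[str, int] = {}
    if config.plant_within_blocks:
        rng_global = substream(config.seed, "plant-blocks")
        for omic, pool in pools.items():
            block_ids = sorted({blocks[f] for f in pool})
            order = rng_global.permutation(block_ids)
            by_block = {b: [f for f in pool if blocks[f] == b] for b in block_ids}
            global_order[omic] = [f for b in order for f in by_block[b]]
            offsets[omic] = 0

    for gene in targets:
        rng = substream(config.seed, "plant", gene)
        for omic, k in config.k_by_omic.items():
            if k == 0:
                continue
            pool = pools[omic]
            if config.plant_within_blocks:
                candidates = global_order[omic][offsets[omic]:] + global_order[omic][: offsets[omic]]
            else:
                candidates = list(rng.permutation(pool))
            n_shared = round(config.shared_fraction * k)
            cursor = 0

            def take(count: int) -> list[str]:
                nonlocal cursor
                if config.plant_within_blocks and cursor % bs:
                    cursor += bs - cursor % bs  # advance to a fresh block
                chunk = candidates[cursor : cursor + count]
                cursor += count
                if len(chunk) < count:
                    raise ConfigError(f"not enough {omic} features to plant k={k}")
                return chunk

            def coefs_for(chunk: list[str]) -> list[tuple[str, float]]:
                mags = rng.uniform(config.coef_min, config.coef_max, size=len(chunk))
                if config.plant_within_blocks:
                    signs = np.full(len(chunk), 1.0 if rng.random() < 0.5 else -1.0)
                else:
                    signs = np.where(rng.random(len(chunk)) < 0.5, 1.0, -1.0)
                return list(zip(chunk, signs * mags))

            shared = coefs_for(take(n_shared)) if n_shared else []
            for ph in config.phenotype_order:
                own = coefs_for(take(k - n_shared)) if k > n_shared else []
                planted[(ph, gene)].extend(shared + own)
            if config.plant_within_blocks:
                used = cursor + (bs - cursor % bs if cursor % bs else 0)
                offsets[omic] = (offsets[omic] + used) % len(global_order[omic])
    return planted


def _signal_variance(coefs: list[tuple[str, float]], blocks: Mapping[str, int], rho: float) -> float:
    """Population variance of sum(beta_j x_j) under unit-variance features
    with equicorrelation rho inside blocks and independence across them."""
    total = sum(c * c for _, c in coefs)
    if rho > 0:
        by_block: dict[int, list[float]] = {}
        for fid, c in coefs:
            by_block.setdefault(blocks[fid], []).append(c)
        for vals in by_block.values():
            s = sum(vals)
            total += rho * (s * s - sum(v * v for v in vals))
    return total


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig) -> tuple[MultiOmicDataset, GroundTruth]:
    """Draw one multi-omic dataset plus its ground truth."""
    feature_ids, feature_omic, targets = _feature_ids(config)
    blocks = _assign_blocks(config, feature_ids, feature_omic, targets)
    planted_sets = _plant_sets(config, feature_ids, feature_omic, targets, blocks)
    row_of = {f: i for i, f in enumerate(feature_ids)}
    m = len(feature_ids)

    # per-block row indices for correlated draws
    block_rows: dict[int, list[int]] = {}
    for fid, b in blocks.items():
        if b >= 0:
            block_rows.setdefault(b, []).append(row_of[fid])

    planted_coefficients: dict[tuple[str, str], list[tuple[str, float]]] = {}
    intercepts: dict[tuple[str, str], float] = {}
    noise_sds: dict[tuple[str, str], float] = {}

    intercept_rngs = {g: substream(config.seed, "intercept", g) for g in targets}

    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    sample_phenotype: list[str] = []

    for ph in config.phenotype_order:
        n = config.n_samples[ph]
        rng = substream(config.seed, "matrix", ph)
        X = np.empty((m, n))
        for b, rows in sorted(block_rows.items()):
            eps = rng.standard_normal((len(rows), n))
            if config.rho > 0 and len(rows) > 1:
                shared = rng.standard_normal(n)
                X[rows, :] = math.sqrt(config.rho) * shared + math.sqrt(1.0 - config.rho) * eps
            else:
                X[rows, :] = eps
        # hub miRNAs get a larger dynamic range; their (weak) linear
        # coefficient then remains the smallest fitted effect while staying
        # statistically detectable.
        for hub_id in (TUMOR_HUB, NORMAL_HUB):
            X[row_of[hub_id], :] *= config.hub_sd

        hub = NORMAL_HUB if ph == config.normal_phenotype else TUMOR_HUB
        for gene in targets:
            coefs = list(planted_sets[(ph, gene)])
            if config.hub_scale > 0:
                coefs.append((hub, config.hub_scale))
            beta0 = intercept_rngs[gene].normal(0.0, 1.0)
            # hubs have sd hub_sd, so their variance share scales accordingly
            var_coefs = [
                (f, c * config.hub_sd if f in (TUMOR_HUB, NORMAL_HUB) else c)
                for f, c in coefs
            ]
            var_signal = _signal_variance(var_coefs, blocks, config.rho)
            sigma = math.sqrt(var_signal * (1.0 - config.r_squared) / config.r_squared)
            noise = substream(config.seed, "noise", ph, gene).standard_normal(n) * sigma
            y = beta0 + noise
            for fid, c in coefs:
                y = y + c * X[row_of[fid], :]
            X[row_of[gene], :] = y
            planted_coefficients[(ph, gene)] = coefs
            intercepts[(ph, gene)] = beta0
            noise_sds[(ph, gene)] = sigma

        # differential-expression pattern of the hubs (shift expressed in
        # units of the hub sd), applied after the responses so it does not
        # perturb E[y]; invisible to the (standardizing) fitting stage.
        if ph != config.normal_phenotype:
            shift = config.hub_de_shift_sds * config.hub_sd
            X[row_of[TUMOR_HUB], :] += shift
            X[row_of[NORMAL_HUB], :] -= shift

        if config.logit_normal_methylation:
            cpg_rows = [row_of[f] for f, o in zip(feature_ids, feature_omic) if o == "methylation"]
            X[cpg_rows, :] = 1.0 / (1.0 + np.exp(-X[cpg_rows, :]))

        columns.append(X)
        sample_ids.extend(f"{ph}_s{i:04d}" for i in range(n))
        sample_phenotype.extend([ph] * n)

    dataset = MultiOmicDataset(
        values=np.concatenate(columns, axis=1),
        feature_ids=feature_ids,
        feature_omic=feature_omic,
        sample_ids=sample_ids,
        sample_phenotype=sample_phenotype,
        target_genes=targets,
    )
    truth = GroundTruth(
        planted_coefficients=planted_coefficients,
        intercepts=intercepts,
        noise_sd=noise_sds,
        tumor_hub_id=TUMOR_HUB,
        normal_hub_id=NORMAL_HUB,
        hub_coefficient_scale=config.hub_scale,
        block_assignments=blocks,
        feature_omic=dict(zip(feature_ids, feature_omic)),
        target_genes=targets,
        normal_phenotype=config.normal_phenotype,
        db_true_positive_fraction=config.db_true_positive_fraction,
    )
    truth.validate(dataset)
    return dataset, truth


def simulate_known_links(truth: GroundTruth, config: SimulationConfig) -> KnownLinkDB:
    """Build a reference link table holding a controlled fraction of the
    planted pairs, padded with random decoy links among measured features."""
    rng = substream(config.seed, "links")
    planted = sorted(truth.planted_pairs(include_hubs=True))
    n_true = round(config.db_true_positive_fraction * len(planted))
    idx = rng.choice(len(planted), size=n_true, replace=False) if planted else []
    true_links = [planted[i] for i in sorted(idx)]

    db_size = config.db_size if config.db_size is not None else len(planted)
    n_decoy = max(0, db_size - n_true)
    links = list(true_links)
    if n_decoy > 0:
        # decoy regulators come from never-planted features so that a
        # fraction-0 table is genuinely independent of model selections
        # (decoys drawn among planted features would anti-correlate the
        # reference with the planted truth)
        planted_features = {f for f, _ in planted}
        features = sorted(
            f
            for f in truth.feature_omic
            if f not in truth.target_genes and f not in planted_features
        )
        candidates = [(f, g) for f in features for g in truth.target_genes]
        idx = rng.choice(len(candidates), size=min(n_decoy, len(candidates)), replace=False)
        links.extend(candidates[i] for i in sorted(idx))

    records = pd.DataFrame(
        {
            "regulator": [r for r, _ in links],
            "target": [t for _, t in links],
            "evidence": [EVIDENCE_KINDS[i % 2] for i in range(len(links))],
            "source": ["sim"] * len(links),
        }
    )
    return KnownLinkDB(records=records)


def simulate_function_sets(truth: GroundTruth, config: SimulationConfig) -> dict[str, set[str]]:
    """One on-target set per gene (covering most of its planted transcript
    predictors, padded with fillers) plus size-matched random background
    sets.  Mutates ``truth.planted_function_sets``."""
    rng = substream(config.seed, "genesets")
    target_set = set(truth.target_genes)
    pool = sorted(
        f for f, o in truth.feature_omic.items() if o == "transcript" and f not in target_set
    )
    sets: dict[str, set[str]] = {}
    for gene in truth.target_genes:
        planted_tx = sorted(
            {
                f
                for (ph, g), coefs in truth.planted_coefficients.items()
                if g == gene
                for f, _ in coefs
                if truth.feature_omic[f] == "transcript"
            }
        )
        n_keep = math.ceil(config.ontarget_coverage * len(planted_tx))
        keep = list(rng.choice(planted_tx, size=n_keep, replace=False)) if planted_tx else []
        size = max(config.ontarget_set_size, n_keep)
        fillers_pool = [f for f in pool if f not in set(planted_tx)]
        fillers = list(rng.choice(fillers_pool, size=size - n_keep, replace=False))
        name = f"ONTARGET_{gene}"
        sets[name] = set(keep) | set(fillers)
        truth.planted_function_sets[gene] = name
    for i in range(config.n_background_sets):
        members = rng.choice(pool, size=config.ontarget_set_size, replace=False)
        sets[f"BG_{i:03d}"] = set(members)
    return sets
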