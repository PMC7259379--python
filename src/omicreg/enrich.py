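"""Hypergeometric gene-set enrichment and cross-phenotype exclusivity.

Selected transcript predictors of each gene are tested for
over-representation in a gene-set collection against a measured-transcript
universe; selections of the same gene in two phenotypes are tested for
being more disjoint than independence predicts (Fisher, alternative
``less`` on the joint cell).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

from scipy import stats as sps

from .errors import DataError
from .fitting import GeneModel
from .io import MultiOmicDataset, logger
from .links import EnrichmentTest, fisher_exact
from .stats import bh_adjust

MIN_SET_SIZE = 2  # floor must admit two-member sets


@dataclass
class FunctionalResult:
    gene: str
    phenotype: str
    set_name: str
    universe_size: int
    set_size: int
    selection_size: int
    overlap: int
    pvalue: float
    qvalue: float = float("nan")


def hypergeom_enrich(
    selection: set[str],
    sets: Mapping[str, set[str]],
    universe: set[str],
    gene: str = "",
    phenotype: str = "",
    min_set_size: int = MIN_SET_SIZE,
) -> list[FunctionalResult]:
    """Upper-tail hypergeometric test of ``selection`` against each set.

    Sets are intersected with the universe first; sets smaller than
    ``min_set_size`` after intersection are skipped.  BH adjustment spans
    the tested sets.
    """
    if not selection:
        logger.info("empty selection for (%s, %s); no enrichment computed", gene, phenotype)
        return []
    stray = selection - universe
    if stray:
        raise DataError(f"selection not contained in universe (e.g. {sorted(stray)[0]!r})")
    n_univ = len(universe)
    n_sel = len(selection)
    results: list[FunctionalResult] = []
    for name, members in sets.items():
        members = members & universe
        if len(members) < min_set_size:
            continue
        overlap = len(selection & members)
        p = float(sps.hypergeom.sf(overlap - 1, n_univ, len(members), n_sel))
        results.append(
            FunctionalResult(
                gene=gene,
                phenotype=phenotype,
                set_name=name,
                universe_size=n_univ,
                set_size=len(members),
                selection_size=n_sel,
                overlap=overlap,
                pvalue=min(p, 1.0),
            )
        )
    qs = bh_adjust([r.pvalue for r in results])
    for r, q in zip(results, qs):
        r.qvalue = float(q)
    return results


def exclusivity_test(
    selection_a: set[str], selection_b: set[str], universe: set[str]
) -> EnrichmentTest:
    """Fisher test for the two selections overlapping less than expected."""
    for sel, lab in ((selection_a, "A"), (selection_b, "B")):
        if sel - universe:
            raise DataError(f"selection {lab} not contained in universe")
    a = len(selection_a & selection_b)
    b = len(selection_a) - a
    c = len(selection_b) - a
    d = len(universe) - a - b - c
    odds, p = fisher_exact(((a, b), (c, d)), alternative="less")
    return EnrichmentTest(
        scope="exclusivity",
        table=(a, b, c, d),
        odds_ratio=odds,
        alternative="less",
        pvalue=p,
    )


def transcript_universe(
    models: Sequence[GeneModel],
    dataset: MultiOmicDataset,
    exclude_targets: bool = True,
) -> set[str]:
    """Measured transcript features eligible as enrichment material."""
    universe = set(dataset.features_of("transcript"))
    if exclude_targets:
        universe -= set(dataset.target_genes)
    return universe


def transcript_selection(model: GeneModel, universe: set[str]) -> set[str]:
    """The model's selected transcript predictors, restricted to the universe."""
    return set(model.selected_by_omic.get("transcript", [])) & universe


def enrich_all(
    models: Sequence[GeneModel],
    sets: Mapping[str, set[str]],
    dataset: MultiOmicDataset,
    exclude_targets: bool = True,
) -> list[FunctionalResult]:
    """Enrichment of each model's selected transcripts, BH per (gene, phenotype)."""
    universe = transcript_universe(models, dataset, exclude_targets=exclude_targets)
    results: list[FunctionalResult] = []
    for m in models:
        selection = transcript_selection(m, universe)
        results.extend(
            hypergeom_enrich(selection, sets, universe, gene=m.gene, phenotype=m.phenotype)
        )
    return results


def exclusivity_all(models: Sequence[GeneModel]) -> list[EnrichmentTest]:
    """Pairwise cross-phenotype exclusivity per gene.

    The candidate universe for a gene is the union of its selected
    transcript predictors over all phenotypes; BH adjustment spans all
    tested pairs.
    """
    by_gene: dict[str, dict[str, set[str]]] = {}
    for m in models:
        by_gene.setdefault(m.gene, {})[m.phenotype] = set(
            m.selected_by_omic.get("transcript", [])
        )
    tests: list[EnrichmentTest] = []
    for gene, by_ph in sorted(by_gene.items()):
        universe = set().union(*by_ph.values())
        if not universe:
            continue
        for pa, pb in combinations(sorted(by_ph), 2):
            if not by_ph[pa] or not by_ph[pb]:
                continue
            t = exclusivity_test(by_ph[pa], by_ph[pb], universe)
            t.scope = f"exclusivity:{gene}:{pa}|{pb}"
            tests.append(t)
    qs = bh_adjust([t.pvalue for t in tests])
    for t, q in zip(tests, qs):
        t.qvalue = float(q)
    return tests


def functional_frame(results: Sequence[FunctionalResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "phenotype": r.phenotype,
                "set": r.set_name,
                "universe": r.universe_size,
                "set_size": r.set_size,
                "selection": r.selection_size,
                "overlap": r.overlap,
                "p": r.pvalue,
                "q": r.qvalue,
            }
            for r in results
        ]
    )
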