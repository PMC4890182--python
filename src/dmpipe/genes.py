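"""Gene-level and gene-set enrichment of significant CpGs.

A gene is called when it carries more significant CpGs than expected
under a binomial model with the array-wide significant-CpG rate; the
resulting gene lists are then tested against named gene-set collections
with one-sided Fisher's exact tests. Both stages are run separately for
hyper- and hypomethylated CpGs and corrected by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSetCollection, ProbeAnnotation
from .dmp import bh_fdr

logger = logging.getLogger(__name__)


def probes_by_gene(annotation: ProbeAnnotation, probe_universe: pd.Index) -> dict[str, list[str]]:
    """Map gene symbol -> probe ids, restricted to a probe universe.

    Probes annotated to several genes count once per gene; intergenic
    probes appear under no gene (they still belong to the CpG universe
    that sets the background rate).
    """
    universe = set(probe_universe)
    mapping: dict[str, list[str]] = {}
    sub = annotation.table.loc[annotation.table.index.isin(universe), "genes"]
    for probe_id, raw in sub.items():
        if not isinstance(raw, str) or not raw:
            continue
        for gene in raw.split(";"):
            mapping.setdefault(gene, []).append(probe_id)
    return mapping


def gene_binomial_test(
    dmps: pd.DataFrame,
    annotation: ProbeAnnotation,
    stratum: str,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene one-sided binomial test for excess significant CpGs.

    The background rate pi is the fraction of all CpGs in the universe
    that are significant in the requested direction stratum ("hyper" or
    "hypo"); each gene with n CpGs and x significant gets
    p = P(X >= x | n, pi), BH-corrected across genes.
    """
    if stratum not in ("hyper", "hypo"):
        raise ValueError(f"stratum must be 'hyper' or 'hypo', got {stratum!r}")
    universe = dmps.index
    sig = set(dmps.index[dmps["dmp"] & (dmps["direction"] == stratum)])
    pi = len(sig) / len(universe) if len(universe) else 0.0
    if pi == 0:
        logger.warning("gene_binomial_test(%s): no significant CpGs; all p = 1", stratum)
    mapping = probes_by_gene(annotation, universe)
    rows = []
    for gene in sorted(mapping):
        probes = mapping[gene]
        n = len(probes)
        x = sum(1 for pr in probes if pr in sig)
        p = 1.0 if pi == 0 else float(stats.binom.sf(x - 1, n, pi))
        rows.append({"gene": gene, "n_cpgs_total": n, "n_cpgs_significant": x, "p": p})
    result = pd.DataFrame(rows, columns=["gene", "n_cpgs_total", "n_cpgs_significant", "p"])
    if len(result):
        result["q"] = bh_fdr(result["p"].to_numpy())
    else:
        result["q"] = pd.Series(dtype=float)
    result["stratum"] = stratum
    result["significant"] = result["q"] < q_threshold
    return result


def fisher_gsea(
    significant_genes: set[str],
    universe: set[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of a gene list in each named set.

    Per set S the 2x2 table over the universe (membership in S x
    membership in the significant list) is tested for enrichment via the
    hypergeometric upper tail; the sample odds ratio is reported and BH
    correction applied across sets. Degenerate margins (empty or
    saturated rows/columns) give p = 1 with the odds ratio flagged NaN.
    """
    if not universe:
        raise ValueError("fisher_gsea: empty gene universe")
    extra = significant_genes - universe
    if extra:
        raise ValueError(f"fisher_gsea: {len(extra)} significant genes outside the universe")
    N = len(universe)
    n = len(significant_genes)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe
        K = len(members)
        k = len(members & significant_genes)
        degenerate = K == 0 or K == N or n == 0 or n == N
        if degenerate:
            p, oratio = 1.0, np.nan
        else:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            n11, n10, n01, n00 = k, K - k, n - k, N - K - n + k
            oratio = np.inf if n10 * n01 == 0 else (n11 * n00) / (n10 * n01)
        rows.append(
            {"set_name": name, "set_size": K, "overlap": k, "odds_ratio": oratio, "p": p}
        )
    result = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "odds_ratio", "p"])
    if len(result):
        result["q"] = bh_fdr(result["p"].to_numpy())
        result["significant"] = result["q"] < 0.05
    else:
        result["q"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result
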