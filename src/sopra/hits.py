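"""Well-level hit calling and gene-level siRNA-agreement classification.

A well is a *hit* when at least ``min_features`` of its feature profiles are
significant (default 2): requiring agreement across independent features
removes essentially all neutral-control false positives while arrest-like
phenotypes alter several features at once.

Gene-level classification exploits that different siRNAs against the same
gene should produce the same 'on-target' phenotype. For each gene:

- ``strong``  — every siRNA is a hit and all hit wells share the same
  membership vector *and* heatmap group;
- ``medium``  — hit siRNAs agree on the heatmap group but not on the exact
  cluster vector, or agreement is perfect but some of the gene's siRNAs are
  not hits (partial coverage caps the class at medium);
- ``weak``    — hit siRNAs land in different heatmap groups, suggesting
  off-target effects or experimental variation;
- ``none``    — no siRNA of the gene is a hit.

Coverage (hit siRNAs / total siRNAs) is always reported rather than silently
demoting the class further.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "WellHit",
    "GeneSummary",
    "DEFAULT_MIN_FEATURES",
    "call_well_hits",
    "summarize_genes",
    "write_hit_report",
    "read_hit_report",
]

DEFAULT_MIN_FEATURES = 2


@dataclass
class WellHit:
    key: tuple  # (plate, well)
    n_significant_features: int
    is_hit: bool
    membership_vector: str = ""
    heatmap_group: int | None = None
    rna_id: str | None = None
    gene: str | None = None
    content: str = ""
    cluster_by_feature: dict = field(default_factory=dict)


@dataclass
class GeneSummary:
    gene: str
    rna_ids: tuple[str, ...]
    hit_class: str  # strong | medium | weak | none
    coverage: float  # hit siRNAs / total siRNAs
    vectors: tuple[str, ...]
    groups: tuple[int, ...]
    cluster_frequency: dict  # feature -> {cluster id: count over the gene's hit wells}


def call_well_hits(
    sig_table: pd.DataFrame,
    min_features: int = DEFAULT_MIN_FEATURES,
    membership: Mapping[tuple, str] | None = None,
    groups: Mapping[tuple, int] | None = None,
    clusters: Mapping[tuple, Mapping[str, int]] | None = None,
) -> list[WellHit]:
    """Count significant features per well and apply the >= min_features rule.

    ``sig_table`` is the frame from :func:`sopra.sigreg.run_sigreg`. Optional
    maps attach membership vectors, heatmap groups and per-feature cluster
    ids (keyed by (plate, well)) to the hits.
    """
    hits = []
    for (plate, well), sub in sig_table.groupby(["plate", "well"], sort=True):
        key = (plate, well)
        n_sig = int(sub["significant"].sum())
        first = sub.iloc[0]
        hits.append(
            WellHit(
                key=key,
                n_significant_features=n_sig,
                is_hit=n_sig >= min_features,
                membership_vector=(membership or {}).get(key, ""),
                heatmap_group=(groups or {}).get(key),
                rna_id=first["rna_id"],
                gene=first["gene"],
                content=first["content"],
                cluster_by_feature=dict((clusters or {}).get(key, {})),
            )
        )
    return hits


def summarize_genes(well_hits: Sequence[WellHit]) -> list[GeneSummary]:
    """Aggregate well hits to genes and classify siRNA agreement.

    Only sample wells with a gene annotation participate; wells of the same
    siRNA (replicate plates) are first reduced to the siRNA level (an siRNA
    is a hit if any of its wells is). Classification is order-invariant in
    the gene's siRNAs.
    """
    by_gene: dict[str, dict[str, list[WellHit]]] = {}
    for h in well_hits:
        if pd.isna(h.gene) or pd.isna(h.rna_id) or not h.gene or not h.rna_id:
            continue
        by_gene.setdefault(h.gene, {}).setdefault(h.rna_id, []).append(h)

    summaries = []
    for gene in sorted(by_gene):
        sirnas = by_gene[gene]
        rna_ids = tuple(sorted(sirnas))
        hit_wells = [h for wells in sirnas.values() for h in wells if h.is_hit]
        hit_sirnas = {rna for rna, wells in sirnas.items() if any(h.is_hit for h in wells)}
        coverage = len(hit_sirnas) / len(rna_ids)
        vectors = tuple(sorted({h.membership_vector for h in hit_wells}))
        groups = tuple(sorted({h.heatmap_group for h in hit_wells if h.heatmap_group is not None}))
        if not hit_sirnas:
            hit_class = "none"
        elif len(groups) > 1:
            hit_class = "weak"
        elif len(vectors) > 1:
            hit_class = "medium"
        else:
            hit_class = "strong" if coverage == 1.0 else "medium"
        freq: dict[str, dict[int, int]] = {}
        for h in hit_wells:
            for feature, cluster in h.cluster_by_feature.items():
                freq.setdefault(feature, {})
                freq[feature][cluster] = freq[feature].get(cluster, 0) + 1
        summaries.append(
            GeneSummary(
                gene=gene,
                rna_ids=rna_ids,
                hit_class=hit_class,
                coverage=coverage,
                vectors=vectors,
                groups=groups,
                cluster_frequency=freq,
            )
        )
    return summaries


def _freq_str(freq: Mapping[str, Mapping[int, int]]) -> str:
    parts = []
    for feature in sorted(freq):
        counts = ";".join(f"c{c}:{n}" for c, n in sorted(freq[feature].items()))
        parts.append(f"{feature}={counts}")
    return "|".join(parts)


def write_hit_report(summaries: Sequence[GeneSummary], path: str | Path) -> pd.DataFrame:
    """Write the gene-level hit report (one row per gene) as a TSV."""
    df = pd.DataFrame(
        {
            "gene": [s.gene for s in summaries],
            "rna_ids": [",".join(s.rna_ids) for s in summaries],
            "hit_class": [s.hit_class for s in summaries],
            "coverage": [s.coverage for s in summaries],
            "vectors": [",".join(s.vectors) for s in summaries],
            "groups": [",".join(map(str, s.groups)) for s in summaries],
            "cluster_frequency": [_freq_str(s.cluster_frequency) for s in summaries],
        }
    )
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return df


def read_hit_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8")
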