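"""ASV filtering, rank collapse, minor-taxon aggregation and Hellinger PCA.

The pipeline mirrors standard amplicon practice: drop non-target ASVs
(organellar 16S, off-domain, domain-unclassified), collapse to a taxonomic
rank with unclassified bins named after the deepest classified parent,
optionally merge rare taxa into an "Other genera" bin for display, then
ordinate with PCA on Hellinger-transformed abundances (the Legendre–Gallagher
recipe: sqrt of relative abundances, column-centred PCA, no column scaling).
Every step conserves per-sample totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import RANKS, AbundanceTable, Lineage, to_relative

__all__ = [
    "FilterAudit",
    "OrdinationResult",
    "filter_asvs",
    "collapse_to_rank",
    "aggregate_minor",
    "hellinger",
    "pca",
    "OTHER_LABEL",
]

#: Display bin for taxa below the aggregation threshold in every sample.
OTHER_LABEL = "Other genera"

#: Lineage names flagging organellar 16S sequences at any rank.
ORGANELLE_NAMES = ("chloroplast", "mitochondria")


@dataclass
class FilterAudit:
    """Bookkeeping from filter_asvs: what was kept and why taxa were dropped."""

    n_input: int
    n_retained: int
    n_off_domain: int
    n_unclassified_domain: int
    n_organelle: int
    empty_result: bool


def filter_asvs(
    t: AbundanceTable, domain_keep: str = "Bacteria", renormalize: bool = True
) -> tuple[AbundanceTable, FilterAudit]:
    """Retain taxa classified to ``domain_keep``, dropping organellar reads.

    A taxon is removed if its domain differs from ``domain_keep`` (Archaea,
    Eukarya), if it is unclassified at domain, or if any rank of its lineage
    is Chloroplast or Mitochondria (organellar 16S amplified alongside the
    bacterial community).  An empty result is legal and flagged in the audit.

    Counts tables keep their retained counts untouched.  A relative table no
    longer sums to 1 after filtering, so it is re-closed over the retained
    taxa (``renormalize=True``, the default) or returned with its values
    preserved but the mode demoted to counts (``renormalize=False``).
    """
    keep: list[str] = []
    n_off = n_unclass = n_org = 0
    target = domain_keep.casefold()
    for taxon in t.taxon_ids:
        lin = t.lineage_of.get(taxon)
        domain = lin.name_at("domain") if lin is not None else None
        if any(lin is not None and lin.contains(org) for org in ORGANELLE_NAMES):
            n_org += 1
        elif domain is None:
            n_unclass += 1
        elif domain.casefold() != target:
            n_off += 1
        else:
            keep.append(taxon)
    audit = FilterAudit(
        n_input=t.n_taxa,
        n_retained=len(keep),
        n_off_domain=n_off,
        n_unclassified_domain=n_unclass,
        n_organelle=n_org,
        empty_result=not keep,
    )
    data = t.data[keep].copy()
    mode = t.mode
    if t.mode == "relative":
        sums = data.sum(axis=1)
        if renormalize and keep and (sums > 0).all():
            data = data.div(sums, axis=0)
        else:
            mode = "counts"  # values preserved; rows no longer close to 1
    out = AbundanceTable(
        data=data,
        mode=mode,
        lineage_of={k: v for k, v in t.lineage_of.items() if k in set(keep)},
        sample_meta={k: dict(v) for k, v in t.sample_meta.items()},
    )
    return out, audit


def _collapse_key(lin: Lineage | None, rank: str) -> tuple[tuple[str, ...], str]:
    """Grouping key (full lineage prefix) and display name for one taxon."""
    if lin is not None and lin.is_classified_at(rank):
        prefix = lin.prefix_to(rank)
        return prefix, prefix[-1]
    deepest = lin.deepest_name if lin is not None else None
    parent = deepest if deepest else "Unclassified"
    prefix = lin.prefix_to(rank) if lin is not None else ()
    return prefix + ("__unclassified__",), f"unclassified_{parent}"


def collapse_to_rank(t: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum taxa sharing the same lineage prefix down to ``rank``.

    Taxa unclassified at ``rank`` are binned as ``unclassified_<name>`` after
    their deepest classified parent (e.g. an ASV known only to family
    Bacillaceae becomes ``unclassified_Bacillaceae``).  Per-sample totals are
    conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    groups: dict[tuple[str, ...], list[str]] = {}
    names: dict[tuple[str, ...], str] = {}
    for taxon in t.taxon_ids:
        key, name = _collapse_key(t.lineage_of.get(taxon), rank)
        groups.setdefault(key, []).append(taxon)
        names[key] = name

    # Distinct lineage prefixes may share a terminal name (homonyms); keep
    # ids unique by suffixing subsequent occurrences with the prefix.
    used: dict[str, int] = {}
    cols: dict[str, pd.Series] = {}
    lineage_of: dict[str, Lineage] = {}
    for key, members in groups.items():
        name = names[key]
        if name in used:
            used[name] += 1
            name = f"{name}_{used[names[key]]}"
        else:
            used[name] = 1
        cols[name] = t.data[members].sum(axis=1)
        lin = t.lineage_of.get(members[0])
        if lin is not None:
            lineage_of[name] = lin.truncated(rank)
    data = pd.DataFrame(cols, index=t.data.index)
    return AbundanceTable(
        data=data, mode=t.mode, lineage_of=lineage_of,
        sample_meta={k: dict(v) for k, v in t.sample_meta.items()},
    )


def aggregate_minor(t: AbundanceTable, threshold_pct: float) -> AbundanceTable:
    """Merge taxa never reaching ``threshold_pct`` into a single "Other genera" bin.

    A taxon is retained iff its relative abundance is >= the threshold in at
    least one sample ("reaching" read inclusively); all others are summed
    into :data:`OTHER_LABEL`.  Per-sample totals are conserved; the operation
    is idempotent.
    """
    if not (0 < threshold_pct < 100):
        raise ValueError(f"threshold_pct must lie in (0, 100), got {threshold_pct}")
    if t.mode != "relative":
        raise ValueError("aggregate_minor requires a relative-mode table")
    thresh = threshold_pct / 100.0
    peak = t.data.max(axis=0)
    major = [tax for tax in t.taxon_ids
             if tax == OTHER_LABEL or peak[tax] >= thresh]
    minor = [tax for tax in t.taxon_ids if tax not in set(major)]
    if not minor:
        return t.copy_with()
    data = t.data[major].copy()
    other = t.data[minor].sum(axis=1)
    if OTHER_LABEL in data.columns:
        data[OTHER_LABEL] = data[OTHER_LABEL] + other
    else:
        data[OTHER_LABEL] = other
    lineage_of = {k: v for k, v in t.lineage_of.items() if k in set(major)}
    return AbundanceTable(
        data=data, mode="relative", lineage_of=lineage_of,
        sample_meta={k: dict(v) for k, v in t.sample_meta.items()},
    )


def hellinger(t: AbundanceTable) -> pd.DataFrame:
    """Hellinger transform: square root of relative abundances.

    Counts are converted internally.  Each transformed row has Euclidean
    norm 1, so Euclidean distances between rows equal Hellinger distances —
    the standard preparation for PCA of compositional community data.
    """
    rel = t if t.mode == "relative" else to_relative(t)
    return np.sqrt(rel.data)


@dataclass
class OrdinationResult:
    """PCA scores and variance decomposition.

    ``axis_variance_fraction`` is non-increasing and sums to <= 1 over the
    computed axes; ``degenerate`` flags all-identical input (zero total
    variance), where fractions are reported as 0.
    """

    sample_scores: pd.DataFrame
    axis_variance_fraction: np.ndarray
    taxon_loadings: pd.DataFrame | None = None
    degenerate: bool = False

    @property
    def n_axes(self) -> int:
        return self.sample_scores.shape[1]


def pca(m: pd.DataFrame, n_axes: int = 2) -> OrdinationResult:
    """Column-centred PCA of a (transformed) samples x taxa matrix.

    No column scaling is applied (the Hellinger transform already fixes the
    row geometry).  Axis signs follow a deterministic convention: the
    largest-magnitude taxon loading on each axis is positive, so score
    tables reproduce across runs and BLAS builds.
    """
    if m.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    max_axes = min(m.shape[0] - 1, m.shape[1])
    if not (1 <= n_axes <= max_axes):
        raise ValueError(f"n_axes must lie in [1, {max_axes}], got {n_axes}")
    x = m.values - m.values.mean(axis=0, keepdims=True)
    total_var = float(np.sum(x**2))
    if total_var <= 1e-300:
        scores = pd.DataFrame(
            np.zeros((m.shape[0], n_axes)), index=m.index,
            columns=[f"PC{i + 1}" for i in range(n_axes)],
        )
        return OrdinationResult(
            sample_scores=scores,
            axis_variance_fraction=np.zeros(n_axes),
            taxon_loadings=pd.DataFrame(
                np.zeros((m.shape[1], n_axes)), index=m.columns,
                columns=scores.columns,
            ),
            degenerate=True,
        )
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # Sign convention: flip each axis so its largest-|loading| entry is positive.
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    frac = (s**2) / total_var
    axes = [f"PC{i + 1}" for i in range(n_axes)]
    scores = pd.DataFrame((u * s)[:, :n_axes], index=m.index, columns=axes)
    loadings = pd.DataFrame(vt[:n_axes].T, index=m.columns, columns=axes)
    return OrdinationResult(
        sample_scores=scores,
        axis_variance_fraction=frac[:n_axes],
        taxon_loadings=loadings,
    )
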