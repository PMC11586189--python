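"""Genus-level hydrocarbon-degradation potential from genome-derived coefficients.

The score follows a two-step recipe.  First, for each genus and each marker
set (a degradation function such as alkB alkane monooxygenase or naphthalene
dioxygenase), a coefficient in [0, 1] is computed as the fraction of that
genus's genomes carrying the marker.  Second, a community's potential for a
marker is the coefficient-weighted sum of genus relative abundances,
expressed in percent:

    potential(sample, marker) = 100 * sum_g rel(sample, g) * coeff(g, marker)

Genera without a coefficient (unclassified bins, or absent from the genome
database) contribute zero and are tallied per sample as the unscored
fraction — they stay in the denominator, so the score is a fraction of the
whole community, with a known downward bias for poorly covered clades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AbundanceTable, GenomeTraitTable, MarkerSet

__all__ = [
    "TraitCoefficientTable",
    "PotentialProfile",
    "build_coefficients",
    "estimate_potential",
    "potential_report",
    "read_coefficients",
    "write_coefficients",
]


def _canon(name: str) -> str:
    """Canonical genus key: whitespace-trimmed, case-folded. No fuzzy matching."""
    return name.strip().casefold()


@dataclass
class TraitCoefficientTable:
    """Genus x marker coefficients: fraction of genomes per genus with each marker.

    ``coeff`` is a DataFrame indexed by genus name with one column per marker
    set, every entry in [0, 1].  ``n_genomes`` records how many genomes backed
    each genus's estimate.
    """

    coeff: pd.DataFrame
    n_genomes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.coeff.values
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("coefficients must lie in [0, 1]")
        for genus in self.coeff.index:
            if self.n_genomes.get(genus, 1) < 1:
                raise ValueError(f"genus {genus!r} has no supporting genomes")

    @property
    def genera(self) -> list[str]:
        return list(self.coeff.index)

    @property
    def markers(self) -> list[str]:
        return list(self.coeff.columns)


@dataclass
class PotentialProfile:
    """Per-sample degradation-potential percentages, one column per marker.

    ``unscored_fraction`` is the percent of each sample's relative abundance
    carried by taxa with no coefficient at all (unclassified bins or genera
    missing from the coefficient table); it bounds how much potential could
    be hiding in unscorable taxa.
    """

    potential: pd.DataFrame
    unscored_fraction: pd.Series
    sample_meta: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.potential.values
        if ((vals < -1e-9) | (vals > 100 + 1e-9)).any():
            raise ValueError("potential must lie in [0, 100] percent")
        uf = self.unscored_fraction.values
        if ((uf < -1e-9) | (uf > 100 + 1e-9)).any():
            raise ValueError("unscored_fraction must lie in [0, 100] percent")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.potential.index)

    @property
    def markers(self) -> list[str]:
        return list(self.potential.columns)


def build_coefficients(
    g: GenomeTraitTable, marker_sets: list[MarkerSet]
) -> TraitCoefficientTable:
    """Derive per-genus coefficients from genome-level marker presence.

    For each genus with at least one genome, the coefficient for a marker set
    is (# genomes satisfying the set's combine rule) / (# genomes of the
    genus) — an exact fraction, never smoothed.  Genomes under the
    ``unclassified`` sentinel are excluded: no coefficient can be assigned to
    populations without a genus.
    """
    if not len(g.presence):
        raise ValueError("empty genome-trait table")
    known = set(g.markers)
    for ms in marker_sets:
        missing = [h for h in ms.hmm_ids if h not in known]
        if missing:
            raise ValueError(
                f"marker set {ms.name!r} references unknown columns {missing}"
            )

    genus_groups: dict[str, list[str]] = {}
    for genome in g.genome_ids:
        genus = g.genus_of[genome]
        if genus == GenomeTraitTable.UNCLASSIFIED:
            continue
        genus_groups.setdefault(genus, []).append(genome)

    genera = sorted(genus_groups)
    names = [ms.name for ms in marker_sets]
    coeff = pd.DataFrame(0.0, index=genera, columns=names)
    n_genomes: dict[str, int] = {}
    for genus, genomes in genus_groups.items():
        block = g.presence.loc[genomes]
        n = len(genomes)
        n_genomes[genus] = n
        for ms in marker_sets:
            sub = block[list(ms.hmm_ids)]
            satisfied = sub.any(axis=1) if ms.combine_rule == "any" else sub.all(axis=1)
            coeff.loc[genus, ms.name] = int(satisfied.sum()) / n
    return TraitCoefficientTable(coeff=coeff, n_genomes=n_genomes)


def estimate_potential(
    t: AbundanceTable, c: TraitCoefficientTable
) -> PotentialProfile:
    """Score each sample: 100 x sum over genera of rel abundance x coefficient.

    ``t`` must be in relative mode with taxa already collapsed to genus
    (taxon ids are genus names or ``unclassified_*`` bins).  Genus names are
    joined exactly after whitespace trimming and case folding.  Taxa absent
    from the coefficient table contribute zero potential and accumulate in
    the unscored fraction.
    """
    if t.mode != "relative":
        raise ValueError(
            "abundance table must be in relative mode; apply to_relative() first"
        )
    lookup = {_canon(genus): genus for genus in c.genera}
    weights = np.zeros((t.n_taxa, len(c.markers)))
    scored = np.zeros(t.n_taxa, dtype=bool)
    for j, taxon in enumerate(t.taxon_ids):
        key = _canon(str(taxon))
        if key in lookup:
            weights[j] = c.coeff.loc[lookup[key]].values
            scored[j] = True
    potential = pd.DataFrame(
        100.0 * (t.values @ weights),
        index=t.sample_ids,
        columns=c.markers,
    )
    unscored = pd.Series(
        100.0 * t.values[:, ~scored].sum(axis=1), index=t.sample_ids,
        name="unscored_fraction",
    )
    return PotentialProfile(
        potential=potential,
        unscored_fraction=unscored,
        sample_meta={k: dict(v) for k, v in t.sample_meta.items()},
    )


def potential_report(p: PotentialProfile, group_by: str | None = None) -> pd.DataFrame:
    """Summarise potentials as min/max/mean per marker, optionally per group.

    ``group_by`` names a sample-metadata key (e.g. season, treatment); the
    report then has one block per level, matching how community potentials
    are conventionally reported as ranges across sample groups.
    """
    if not len(p.potential):
        raise ValueError("empty potential profile")
    long = p.potential.reset_index(names="sample_id").melt(
        id_vars="sample_id", var_name="marker", value_name="potential"
    )
    if group_by is None:
        out = long.groupby("marker", sort=False)["potential"].agg(
            ["min", "max", "mean"]
        )
        return out.reset_index()
    groups = {}
    for sid in p.sample_ids:
        meta = p.sample_meta.get(sid, {})
        if group_by not in meta:
            raise KeyError(f"sample {sid!r} lacks metadata key {group_by!r}")
        groups[sid] = meta[group_by]
    long[group_by] = long["sample_id"].map(groups)
    out = long.groupby([group_by, "marker"], sort=False)["potential"].agg(
        ["min", "max", "mean"]
    )
    return out.reset_index()


def write_coefficients(c: TraitCoefficientTable, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# hydrodeg 0.1.0 writer=coefficients\n")
        out = c.coeff.copy()
        out.insert(0, "n_genomes", [c.n_genomes.get(g, 0) for g in out.index])
        out.index.name = "genus"
        out.to_csv(fh, sep="\t", lineterminator="\n")


def read_coefficients(path) -> TraitCoefficientTable:
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    n_genomes = {}
    if "n_genomes" in frame.columns:
        n_genomes = {str(g): int(n) for g, n in frame["n_genomes"].items()}
        frame = frame.drop(columns=["n_genomes"])
    frame.index = frame.index.astype(str)
    frame.index.name = None
    return TraitCoefficientTable(coeff=frame.astype(float), n_genomes=n_genomes)
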