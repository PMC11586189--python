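"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of its parameters and a seed, returns its
output paired with a :class:`SyntheticTruth` record of the ground-truth
parameters (and, where relevant, the realised values), and is bit-exactly
reproducible.  One global seed fans out to fixed per-generator substreams
via ``numpy.random.SeedSequence`` spawn keys, so adding a generator never
perturbs the streams of existing ones.

What is emulated:

* ``gen_community`` — heterogeneous compositional genus tables with
  season/host structure (Dirichlet rows whose concentration vector shifts
  with design factors) and a configurable fraction of taxa unclassified at
  genus;
* ``gen_genome_traits`` — a genome database search result: per-genus marker
  prevalences realised as independent Bernoulli presence calls per genome;
* ``gen_decay`` — first-order decay series with multiplicative log-normal
  noise, the greenhouse naphthalene regime;
* ``gen_flask`` — flask removal assays with heat-killed controls carrying
  their own abiotic loss.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import (
    RANKS,
    AbundanceTable,
    DecayExperiment,
    DecayRecord,
    GenomeTraitTable,
    Lineage,
)

__all__ = [
    "SyntheticTruth",
    "gen_community",
    "gen_genome_traits",
    "gen_decay",
    "gen_flask",
]

# Fixed spawn keys: one substream per generator.
_STREAM = {"community": 0, "traits": 1, "decay": 2, "flask": 3}


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside every generated dataset."""

    seed: int
    kind: str
    params: dict = field(default_factory=dict)


def _rng(seed: int, kind: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAM[kind],))
    )


def _synthetic_lineage(index: int, genus: str | None) -> Lineage:
    """A plausible ranked lineage for synthetic taxon number ``index``.

    Higher ranks are shared in blocks (five genera per family and so on up),
    giving the nested structure rank collapse exercises.  ``genus=None``
    leaves the genus rank unassigned.
    """
    names = [
        "Bacteria",
        f"Phylum{index // 625:03d}",
        f"Class{index // 125:03d}",
        f"Order{index // 25:03d}",
        f"Family{index // 5:03d}",
        genus,
    ]
    return Lineage(tuple(zip(RANKS, names)))


def gen_community(
    n_samples: int,
    n_genera: int,
    concentration: float | np.ndarray = 1.0,
    meta_design: dict[str, list[str]] | None = None,
    seed: int = 0,
    unclassified_fraction: float = 0.1,
    effect_size: float = 1.0,
    genus_names: list[str] | None = None,
) -> tuple[AbundanceTable, SyntheticTruth]:
    """Generate a relative-abundance genus table with factor structure.

    Each sample's composition is Dirichlet(alpha_s) with

        alpha_s = concentration * exp(effect_size * sum_f shift[f, level_f(s)])

    where each (factor, level) pair owns a fixed standard-normal shift vector
    over genera, drawn once from the substream.  ``effect_size = 0`` makes
    all samples exchangeable.  Samples cycle through the Cartesian product
    of ``meta_design`` levels, recorded in sample metadata.  A fraction of
    taxa (the last ones, deterministically) is left unclassified at genus,
    binned as ``unclassified_<family>``.
    """
    if n_samples < 2 or n_genera < 2:
        raise ValueError("need n_samples >= 2 and n_genera >= 2")
    conc = np.broadcast_to(np.asarray(concentration, dtype=float), (n_genera,)).copy()
    if (conc <= 0).any():
        raise ValueError("concentration parameters must be positive")
    if not (0 <= unclassified_fraction <= 1):
        raise ValueError("unclassified_fraction must lie in [0, 1]")
    rng = _rng(seed, "community")

    if genus_names is None:
        genus_names = [f"Genus{i:03d}" for i in range(n_genera)]
    elif len(genus_names) != n_genera:
        raise ValueError("genus_names length must equal n_genera")

    n_unclass = int(round(unclassified_fraction * n_genera))
    lineages: dict[str, Lineage] = {}
    taxon_ids: list[str] = []
    for i in range(n_genera):
        if i < n_genera - n_unclass:
            lin = _synthetic_lineage(i, genus_names[i])
            tid = genus_names[i]
        else:
            lin = _synthetic_lineage(i, None)
            tid = f"unclassified_{lin.name_at('family')}"
        # Distinct unclassified taxa may share a family bin name; disambiguate.
        if tid in lineages:
            tid = f"{tid}_{i}"
        taxon_ids.append(tid)
        lineages[tid] = lin

    meta_design = meta_design or {}
    factors = list(meta_design)
    combos = list(itertools.product(*(meta_design[f] for f in factors))) or [()]
    assignment = [combos[i % len(combos)] for i in range(n_samples)]
    shifts = {
        (f, lev): rng.standard_normal(n_genera)
        for f in factors
        for lev in meta_design[f]
    }

    sample_ids = [f"sample{i:03d}" for i in range(n_samples)]
    rows = np.empty((n_samples, n_genera))
    alphas = {}
    sample_meta: dict[str, dict[str, str]] = {}
    for i, (sid, combo) in enumerate(zip(sample_ids, assignment)):
        shift = np.zeros(n_genera)
        for f, lev in zip(factors, combo):
            shift += shifts[(f, lev)]
        alpha = conc * np.exp(effect_size * shift)
        alphas[sid] = alpha
        rows[i] = rng.dirichlet(alpha)
        sample_meta[sid] = dict(zip(factors, combo))

    table = AbundanceTable(
        data=pd.DataFrame(rows, index=sample_ids, columns=taxon_ids),
        mode="relative",
        lineage_of=lineages,
        sample_meta=sample_meta,
    )
    truth = SyntheticTruth(
        seed=seed,
        kind="community",
        params={
            "n_samples": n_samples,
            "n_genera": n_genera,
            "concentration": conc.tolist(),
            "effect_size": effect_size,
            "unclassified_fraction": unclassified_fraction,
            "meta_design": {f: list(v) for f, v in meta_design.items()},
            "alphas": {sid: a.tolist() for sid, a in alphas.items()},
            "genus_names": list(genus_names),
            "taxon_ids": list(taxon_ids),
        },
    )
    return table, truth


def gen_genome_traits(
    genus_prevalences: dict[str, dict[str, float]],
    genomes_per_genus: int,
    seed: int = 0,
) -> tuple[GenomeTraitTable, SyntheticTruth]:
    """Generate genome-level marker presence from per-genus prevalences.

    Each genus contributes ``genomes_per_genus`` genomes; each genome's
    presence of each marker is an independent Bernoulli draw at the genus
    prevalence.  The truth records both the target prevalences and the
    realised per-genus fractions (the exact quantity ``build_coefficients``
    must recover).
    """
    if genomes_per_genus < 1:
        raise ValueError("genomes_per_genus must be >= 1")
    markers: list[str] = []
    for prev in genus_prevalences.values():
        for m in prev:
            if m not in markers:
                markers.append(m)
    for genus, prev in genus_prevalences.items():
        for m, p in prev.items():
            if not (0 <= p <= 1):
                raise ValueError(f"prevalence {p} for {genus}/{m} outside [0, 1]")
    rng = _rng(seed, "traits")
    genome_ids: list[str] = []
    genus_of: dict[str, str] = {}
    presence_rows = []
    realized: dict[str, dict[str, float]] = {}
    for genus, prev in genus_prevalences.items():
        block = np.zeros((genomes_per_genus, len(markers)), dtype=bool)
        for j, m in enumerate(markers):
            p = prev.get(m, 0.0)
            block[:, j] = rng.random(genomes_per_genus) < p
        for i in range(genomes_per_genus):
            gid = f"{genus}_genome{i:03d}"
            genome_ids.append(gid)
            genus_of[gid] = genus
        presence_rows.append(block)
        realized[genus] = {
            m: float(block[:, j].sum()) / genomes_per_genus
            for j, m in enumerate(markers)
        }
    presence = pd.DataFrame(
        np.vstack(presence_rows), index=genome_ids, columns=markers
    )
    table = GenomeTraitTable(presence=presence, genus_of=genus_of)
    truth = SyntheticTruth(
        seed=seed,
        kind="traits",
        params={
            "genomes_per_genus": genomes_per_genus,
            "target_prevalences": {g: dict(p) for g, p in genus_prevalences.items()},
            "realized_fractions": realized,
        },
    )
    return table, truth


def gen_decay(
    conditions: dict[str, tuple[float, float]],
    times: list[float],
    replicates: int = 2,
    seed: int = 0,
    noise_at_t0: bool = True,
    time_unit: str = "days",
) -> tuple[DecayExperiment, SyntheticTruth]:
    """Generate first-order decay series in residual-percent units.

    ``conditions`` maps a label to ``(half_life, noise_sd_log)``; each
    replicate observes

        residual(t) = 100 * 2^(-t / half_life) * exp(eps),  eps ~ N(0, sd^2)

    With ``noise_at_t0=False`` the t = 0 observations are exactly 100%,
    matching a design where the starting level is the (noise-free) spiked
    amount rather than a measurement.
    """
    if 0 not in [float(t) for t in times]:
        raise ValueError("times must include 0 (the spiking time)")
    for label, (hl, sd) in conditions.items():
        if hl <= 0:
            raise ValueError(f"half-life for {label!r} must be positive")
        if sd < 0:
            raise ValueError(f"noise sd for {label!r} must be non-negative")
    rng = _rng(seed, "decay")
    records = []
    for label, (hl, sd) in conditions.items():
        for t in times:
            for rep in range(replicates):
                mean = 100.0 * 2.0 ** (-float(t) / hl)
                if sd > 0 and (noise_at_t0 or t != 0):
                    mean *= np.exp(rng.normal(0.0, sd))
                records.append(DecayRecord(float(t), label, f"rep{rep}", float(mean)))
    experiment = DecayExperiment(records, time_unit=time_unit,
                                 concentration_unit="percent")
    truth = SyntheticTruth(
        seed=seed,
        kind="decay",
        params={
            "conditions": {
                lab: {"half_life": hl, "noise_sd_log": sd,
                      "rate_per_unit": np.log(2.0) / hl}
                for lab, (hl, sd) in conditions.items()
            },
            "times": [float(t) for t in times],
            "replicates": replicates,
            "noise_at_t0": noise_at_t0,
            "time_unit": time_unit,
        },
    )
    return experiment, truth


def gen_flask(
    removal_true: dict[str, float],
    control_loss_pct: float = 35.0,
    replicates: int = 3,
    noise_sd: float = 0.02,
    seed: int = 0,
    nominal_concentration: float = 50.0,
) -> tuple[dict[str, np.ndarray], np.ndarray, SyntheticTruth]:
    """Generate flask assay concentrations with heat-killed controls.

    Controls sit at ``nominal * (1 - control_loss/100)`` (abiotic loss has
    already acted on them); each strain's flasks sit at the control level
    further reduced by its true removal.  Multiplicative log-normal noise
    (sd on the log scale) applies per replicate.  Defaults follow a
    naphthalene screen: 50 ug/mL nominal spike, 3 replicates, ~35% abiotic
    loss in shaken flasks.
    """
    for strain, r in removal_true.items():
        if not (0 <= r <= 100):
            raise ValueError(f"true removal for {strain!r} outside [0, 100]")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = _rng(seed, "flask")
    control_level = nominal_concentration * (1.0 - control_loss_pct / 100.0)
    controls = control_level * np.exp(rng.normal(0.0, noise_sd, size=replicates))
    samples: dict[str, np.ndarray] = {}
    for strain, r in removal_true.items():
        level = control_level * (1.0 - r / 100.0)
        samples[strain] = level * np.exp(rng.normal(0.0, noise_sd, size=replicates))
    truth = SyntheticTruth(
        seed=seed,
        kind="flask",
        params={
            "removal_true": dict(removal_true),
            "control_loss_pct": control_loss_pct,
            "replicates": replicates,
            "noise_sd": noise_sd,
            "nominal_concentration": nominal_concentration,
        },
    )
    return samples, controls, truth
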