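"""Data model and text I/O for community, genome-trait and decay-experiment tables.

The central container is :class:`AbundanceTable`, a samples x taxa matrix of
counts or relative abundances with per-taxon :class:`Lineage` metadata and
per-sample key/value labels.  Genome-level marker presence lives in
:class:`GenomeTraitTable`, decay time series in :class:`DecayExperiment`.
All readers consume plain TSV (or hmmsearch ``--tblout`` text); all writers
emit TSV with a ``#``-comment provenance header.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "Lineage",
    "AbundanceTable",
    "GenomeTraitTable",
    "MarkerSet",
    "DecayRecord",
    "DecayExperiment",
    "parse_lineage",
    "read_abundance_table",
    "write_abundance_table",
    "to_relative",
    "read_genome_traits",
    "write_genome_traits",
    "read_hmm_hits",
    "traits_from_hits",
    "read_decay_experiment",
    "write_decay_experiment",
]

# Ranks handled for amplicon lineages, shallow to deep.
RANKS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")

#: Prefixes of the ``g__Genus`` style emitted by GTDB/UNITE-flavoured classifiers.
_RANK_PREFIXES = tuple(f"{r[0]}__" for r in RANKS) + ("k__", "d__")

_REL_TOL = 1e-9
_PROVENANCE = "hydrodeg 0.1.0"


# ---------------------------------------------------------------------------
# Lineage


@dataclass(frozen=True)
class Lineage:
    """Ranked taxonomic assignment from domain down to genus.

    ``ranks`` is an ordered tuple of ``(rank_name, taxon_name)`` pairs, one per
    entry of :data:`RANKS`, with ``None`` for unassigned ranks.  A valid
    lineage is classified contiguously from the top: once a rank is
    unassigned, all deeper ranks are unassigned too.
    """

    ranks: tuple[tuple[str, str | None], ...]

    def __post_init__(self) -> None:
        names = tuple(r for r, _ in self.ranks)
        if names != RANKS:
            raise ValueError(f"lineage ranks must be {RANKS}, got {names}")
        seen_gap = False
        for rank, name in self.ranks:
            if name is None or name == "":
                seen_gap = True
            elif seen_gap:
                raise ValueError(
                    f"rank {rank!r} assigned below an unassigned rank in {self.ranks}"
                )

    @property
    def classified_depth(self) -> str | None:
        """Deepest rank with an assignment, or None if fully unclassified."""
        depth = None
        for rank, name in self.ranks:
            if name:
                depth = rank
        return depth

    def name_at(self, rank: str) -> str | None:
        for r, name in self.ranks:
            if r == rank:
                return name
        raise KeyError(rank)

    @property
    def deepest_name(self) -> str | None:
        """Taxon name at the deepest classified rank."""
        last = None
        for _, name in self.ranks:
            if name:
                last = name
        return last

    def prefix_to(self, rank: str) -> tuple[str, ...]:
        """Names from domain down to ``rank`` (exclusive of unassigned)."""
        if rank not in RANKS:
            raise KeyError(rank)
        out: list[str] = []
        for r, name in self.ranks:
            if name:
                out.append(name)
            if r == rank:
                break
        return tuple(out)

    def truncated(self, rank: str) -> "Lineage":
        """Copy with every rank below ``rank`` cleared."""
        if rank not in RANKS:
            raise KeyError(rank)
        cut = RANKS.index(rank)
        return Lineage(
            tuple(
                (r, name if i <= cut else None)
                for i, (r, name) in enumerate(self.ranks)
            )
        )

    def is_classified_at(self, rank: str) -> bool:
        return bool(self.name_at(rank))

    def contains(self, taxon: str) -> bool:
        """True if any rank name equals ``taxon`` case-insensitively."""
        low = taxon.casefold()
        return any(name and name.casefold() == low for _, name in self.ranks)

    def __str__(self) -> str:
        names = [name for _, name in self.ranks if name]
        return ";".join(names)


def parse_lineage(text: str, sep: str = ";") -> Lineage:
    """Parse a semicolon-delimited ranked lineage string.

    Rank prefixes (``d__``, ``g__`` ...) are tolerated and stripped; trailing
    empty fields mark unassigned ranks.  Strings deeper than genus are
    truncated (species epithets are out of scope for genus-level analyses).
    """
    parts = [p.strip() for p in text.split(sep)]
    names: list[str | None] = []
    for p in parts[: len(RANKS)]:
        for pref in _RANK_PREFIXES:
            if p.startswith(pref):
                p = p[len(pref):]
                break
        names.append(p if p else None)
    names.extend([None] * (len(RANKS) - len(names)))
    return Lineage(tuple(zip(RANKS, names)))


# ---------------------------------------------------------------------------
# AbundanceTable


@dataclass
class AbundanceTable:
    """Samples x taxa abundance matrix with lineage and sample metadata.

    ``data`` is a pandas DataFrame indexed by sample id with taxon-id columns.
    ``mode`` is ``"counts"`` or ``"relative"``; in relative mode every row
    sums to 1 within 1e-9.
    """

    data: pd.DataFrame
    mode: str = "counts"
    lineage_of: dict[str, Lineage] = field(default_factory=dict)
    sample_meta: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"mode must be 'counts' or 'relative', got {self.mode!r}")
        self.data = self.data.astype(float)
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate taxon id {dup!r}")
        if (self.data.values < 0).any():
            s, t = np.argwhere(self.data.values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.data.index[s]!r}, "
                f"taxon {self.data.columns[t]!r}"
            )
        if self.mode == "relative":
            sums = self.data.sum(axis=1)
            bad = sums[(sums - 1.0).abs() > _REL_TOL]
            if len(bad):
                raise ValueError(
                    f"relative-mode row sums must be 1: sample {bad.index[0]!r} "
                    f"sums to {bad.iloc[0]!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.values

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **kw) -> "AbundanceTable":
        base = dict(
            data=self.data.copy(),
            mode=self.mode,
            lineage_of=dict(self.lineage_of),
            sample_meta={k: dict(v) for k, v in self.sample_meta.items()},
        )
        base.update(kw)
        return AbundanceTable(**base)


def to_relative(t: AbundanceTable, allow_relative: bool = False) -> AbundanceTable:
    """Convert a counts table to relative abundances (rows summing to 1).

    Already-relative input is an error unless ``allow_relative`` is set, in
    which case it is returned unchanged (making the conversion idempotent).
    """
    if t.mode == "relative":
        if allow_relative:
            return t
        raise ValueError("table already in relative mode (pass allow_relative=True)")
    sums = t.data.sum(axis=1)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total count")
    return t.copy_with(data=t.data.div(sums, axis=0), mode="relative")


def _read_tsv_strict(path) -> pd.DataFrame:
    """Read a TSV, skipping '#' comment lines, erroring on ragged rows."""
    with open(path, "rt", encoding="utf-8") as fh:
        rows: list[list[str]] = []
        width = None
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(cells)} fields, expected {width})"
                )
            rows.append(cells)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    # pandas mangles duplicate headers (x, x.1); catch them on the raw text
    header, body_ids = rows[0][1:], [r[0] for r in rows[1:]]
    for ids in (header, body_ids):
        seen: set[str] = set()
        for name in ids:
            if name in seen:
                raise ValueError(f"{path}: duplicate identifier {name!r}")
            seen.add(name)
    buf = io.StringIO("\n".join("\t".join(r) for r in rows))
    return pd.read_csv(buf, sep="\t", header=0, index_col=0, dtype=str)


def read_abundance_table(
    path,
    dialect: str = "taxa_rows",
    lineage_column: str = "lineage",
) -> AbundanceTable:
    """Read a TSV abundance table.

    ``dialect`` declares the orientation explicitly — ``taxa_rows`` (one row
    per taxon, one column per sample) or ``samples_rows``; there is no
    auto-detection.  An optional lineage column (taxa_rows) or lineage row
    (samples_rows) holds semicolon-delimited ranked lineage strings.  The
    table is returned in counts mode unless every sample sums to 1 within
    1e-9, in which case it is relative.
    """
    if dialect not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = _read_tsv_strict(path)
    lineages: dict[str, Lineage] = {}
    if dialect == "taxa_rows":
        if lineage_column in raw.columns:
            for taxon, text in raw[lineage_column].items():
                if isinstance(text, str) and text.strip():
                    lineages[str(taxon)] = parse_lineage(text)
            raw = raw.drop(columns=[lineage_column])
        data = raw.T
    else:
        if lineage_column in raw.index:
            for taxon, text in raw.loc[lineage_column].items():
                if isinstance(text, str) and text.strip():
                    lineages[str(taxon)] = parse_lineage(text)
            raw = raw.drop(index=[lineage_column])
        data = raw

    if data.index.duplicated().any():
        dup = data.index[data.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate identifier {dup!r}")
    if data.columns.duplicated().any():
        dup = data.columns[data.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate identifier {dup!r}")

    try:
        num = data.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric abundance value ({exc})") from exc
    if num.isna().any().any():
        raise ValueError(f"{path}: missing abundance value")
    if (num.values < 0).any():
        s, t = np.argwhere(num.values < 0)[0]
        raise ValueError(
            f"{path}: negative value at sample {num.index[s]!r}, "
            f"taxon {num.columns[t]!r}"
        )
    sums = num.sum(axis=1)
    mode = "relative" if np.allclose(sums, 1.0, atol=_REL_TOL, rtol=0) else "counts"
    return AbundanceTable(data=num, mode=mode, lineage_of=lineages)


def _provenance_header(params: dict) -> str:
    items = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# {_PROVENANCE} {items}\n"


def write_abundance_table(t: AbundanceTable, path, dialect: str = "taxa_rows") -> None:
    """Write a table as TSV in the declared dialect, with a provenance header."""
    if dialect not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(_provenance_header({"writer": "abundance", "mode": t.mode,
                                     "dialect": dialect}))
        if dialect == "taxa_rows":
            out = t.data.T.copy()
            out.index.name = "taxon_id"
            if t.lineage_of:
                out["lineage"] = [str(t.lineage_of[tax]) if tax in t.lineage_of else ""
                                  for tax in out.index]
        else:
            out = t.data.copy()
            out.index.name = "sample_id"
        out.to_csv(fh, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# GenomeTraitTable and marker sets


@dataclass
class GenomeTraitTable:
    """Genome x marker boolean presence matrix with genome-to-genus labels.

    ``presence`` is a DataFrame indexed by genome id with one boolean column
    per marker/HMM; genomes lacking a genus label carry the sentinel
    ``"unclassified"``.
    """

    presence: pd.DataFrame
    genus_of: dict[str, str]

    UNCLASSIFIED = "unclassified"

    def __post_init__(self) -> None:
        if self.presence.index.duplicated().any():
            dup = self.presence.index[self.presence.index.duplicated()][0]
            raise ValueError(f"duplicate genome id {dup!r}")
        vals = self.presence.values
        if not np.isin(vals, [0, 1, True, False]).all():
            raise ValueError("presence values must be boolean (0/1)")
        self.presence = self.presence.astype(bool)
        for g in self.presence.index:
            self.genus_of.setdefault(str(g), self.UNCLASSIFIED)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def markers(self) -> list[str]:
        return list(self.presence.columns)


@dataclass(frozen=True)
class MarkerSet:
    """A named degradation function backed by one or more HMM profiles.

    ``combine_rule`` says how hits over ``hmm_ids`` combine into presence of
    the function in a genome: ``"any"`` (default; any subunit or homolog
    counts) or ``"all"`` (every profile required, for multi-subunit enzymes).
    """

    name: str
    hmm_ids: tuple[str, ...]
    combine_rule: str = "any"

    def __post_init__(self) -> None:
        if not self.hmm_ids:
            raise ValueError(f"marker set {self.name!r} has no hmm_ids")
        if self.combine_rule not in ("any", "all"):
            raise ValueError(f"combine_rule must be 'any' or 'all', got {self.combine_rule!r}")


def read_genome_traits(path) -> GenomeTraitTable:
    """Read a genome-trait TSV: genome_id, genus, then one 0/1 column per marker."""
    raw = _read_tsv_strict(path)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate genome_id {dup!r}")
    if "genus" not in raw.columns:
        raise ValueError(f"{path}: missing 'genus' column")
    genus_of = {}
    for gid, genus in raw["genus"].items():
        genus = (genus or "").strip() if isinstance(genus, str) else ""
        genus_of[str(gid)] = genus if genus else GenomeTraitTable.UNCLASSIFIED
    markers = raw.drop(columns=["genus"])
    for col in markers.columns:
        bad = ~markers[col].isin(["0", "1"])
        if bad.any():
            gid = markers.index[bad][0]
            raise ValueError(
                f"{path}: non-binary presence value {markers.loc[gid, col]!r} "
                f"for genome {gid!r}, marker {col!r}"
            )
    return GenomeTraitTable(presence=markers.astype(int).astype(bool),
                            genus_of=genus_of)


def write_genome_traits(g: GenomeTraitTable, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(_provenance_header({"writer": "genome_traits"}))
        out = g.presence.astype(int).copy()
        out.insert(0, "genus", [g.genus_of[gid] for gid in out.index])
        out.index.name = "genome_id"
        out.to_csv(fh, sep="\t", lineterminator="\n")


# hmmsearch --tblout full-sequence E-value column (0-based; after target name,
# target accession, query name, query accession).
_TBLOUT_EVALUE_COL = 4
_TBLOUT_QUERY_COL = 2


def read_hmm_hits(
    path,
    evalue_max: float = 1e-5,
    genome_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Parse an hmmsearch ``--tblout``-style hit file into genome x HMM presence.

    Keeps hits with full-sequence E-value <= ``evalue_max`` and maps target
    names to genome ids through ``genome_map`` (identity if omitted).
    Unmappable targets are skipped with a single summary warning; any
    retained hit marks the (genome, HMM) pair present.
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    hits: dict[str, set[str]] = {}
    hmms: list[str] = []
    skipped = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            cells = line.split()
            if len(cells) <= _TBLOUT_EVALUE_COL:
                raise ValueError(f"{path}: truncated hit row at line {lineno}")
            target, query = cells[0], cells[_TBLOUT_QUERY_COL]
            try:
                evalue = float(cells[_TBLOUT_EVALUE_COL])
            except ValueError:
                raise ValueError(
                    f"{path}: malformed E-value {cells[_TBLOUT_EVALUE_COL]!r} "
                    f"at line {lineno}"
                ) from None
            if evalue > evalue_max:
                continue
            if genome_map is not None:
                if target not in genome_map:
                    skipped += 1
                    continue
                genome = genome_map[target]
            else:
                genome = target
            hits.setdefault(genome, set()).add(query)
            if query not in hmms:
                hmms.append(query)
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} hits with unmappable targets",
                      stacklevel=2)
    genomes = sorted(hits)
    table = pd.DataFrame(False, index=genomes, columns=hmms)
    for genome, qs in hits.items():
        table.loc[genome, sorted(qs)] = True
    return table


def traits_from_hits(hits: pd.DataFrame, genus_of: dict[str, str],
                     all_genomes: list[str] | None = None) -> GenomeTraitTable:
    """Build a GenomeTraitTable from a hit presence frame and a genus map.

    ``all_genomes`` lists genomes searched but without hits, so absence is
    recorded (a genome absent from the hit file scored nothing, which is not
    the same as not searched).
    """
    if all_genomes is not None:
        missing = [g for g in all_genomes if g not in hits.index]
        if missing:
            pad = pd.DataFrame(False, index=missing, columns=hits.columns)
            hits = pd.concat([hits, pad]).sort_index()
    return GenomeTraitTable(presence=hits.astype(bool), genus_of=dict(genus_of))


# ---------------------------------------------------------------------------
# DecayExperiment


@dataclass(frozen=True)
class DecayRecord:
    time: float
    condition: str
    replicate: str
    concentration: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", float(self.time))
        object.__setattr__(self, "concentration", float(self.concentration))
        if self.concentration < 0:
            raise ValueError(
                f"negative concentration {self.concentration} "
                f"({self.condition}, rep {self.replicate}, t={self.time})"
            )


@dataclass
class DecayExperiment:
    """Time/condition/replicate concentration records with declared units.

    One time unit and one concentration unit per experiment; units are
    metadata, never converted implicitly.  Each condition must include at
    least one record at the experiment's earliest time, anchoring the 100%
    reference.
    """

    records: list[DecayRecord]
    time_unit: str = "days"
    concentration_unit: str = "percent"

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("experiment has no records")
        t0 = min(r.time for r in self.records)
        for cond in self.conditions:
            if not any(r.condition == cond and r.time == t0 for r in self.records):
                raise ValueError(
                    f"condition {cond!r} has no record at earliest time {t0}"
                )

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for r in self.records:
            if r.condition not in seen:
                seen.append(r.condition)
        return seen

    @property
    def t0(self) -> float:
        return min(r.time for r in self.records)

    def subset(self, condition: str) -> list[DecayRecord]:
        out = [r for r in self.records if r.condition == condition]
        if not out:
            raise ValueError(f"unknown condition {condition!r}")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.time, r.condition, r.replicate, r.concentration) for r in self.records],
            columns=["time", "condition", "replicate", "concentration"],
        )


def read_decay_experiment(path) -> DecayExperiment:
    """Read a decay-experiment TSV (time, condition, replicate, concentration).

    Units may be declared in comment lines ``# time_unit=...`` and
    ``# concentration_unit=...``; defaults are days and percent.
    """
    time_unit, conc_unit = "days", "percent"
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("time_unit="):
                        time_unit = tok.split("=", 1)[1]
                    elif tok.startswith("concentration_unit="):
                        conc_unit = tok.split("=", 1)[1]
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"time", "condition", "replicate", "concentration"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(frame.columns))}")
    records = [
        DecayRecord(float(r.time), str(r.condition), str(r.replicate),
                    float(r.concentration))
        for r in frame.itertuples()
    ]
    return DecayExperiment(records, time_unit=time_unit, concentration_unit=conc_unit)


def write_decay_experiment(e: DecayExperiment, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(_provenance_header({"writer": "decay",
                                     "time_unit": e.time_unit,
                                     "concentration_unit": e.concentration_unit}))
        e.to_frame().to_csv(fh, sep="\t", index=False, lineterminator="\n")
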