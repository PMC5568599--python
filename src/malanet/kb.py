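"""Knowledgebase model: domain types, validation, and plain-text readers/writers.

A knowledgebase is a collection of disease-gene :class:`Association` records,
each backed by one or more source-level :class:`EvidenceItem` assertions, plus
a disease vocabulary (:class:`DiseaseRecord`) and gene-set collections
(:class:`GeneSet`, GMT format).  The :class:`ScoreTable` holds the per-source,
per-annotation-class base scores and every scoring/filtering constant.

All on-disk formats are UTF-8 plain text: tab-separated tables for
associations, diseases and network edges, and standard GMT for gene sets.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .errors import FormatError, ValidationError

ASSOCIATION_COLUMNS = ["disease_id", "gene_symbol", "source", "annotation_class", "publication_id"]
DISEASE_COLUMNS = ["disease_id", "main_name", "aliases"]
EDGE_COLUMNS = ["disease_id", "gene_symbol", "dg_raw", "dg", "gd", "elite"]


@dataclass(frozen=True)
class GeneRef:
    """A gene identifier.  The namespace (HGNC symbol, Ensembl id...) is opaque."""

    symbol: str

    def __post_init__(self) -> None:
        if not self.symbol or any(c.isspace() for c in self.symbol):
            raise ValidationError(f"invalid gene symbol: {self.symbol!r}")
        object.__setattr__(self, "symbol", self.symbol.upper())


@dataclass(frozen=True)
class EvidenceItem:
    """One source-level assertion linking a disease to a gene.

    ``publication_id`` is present only for literature-derived evidence; it is
    the handle the publication promiscuity filter operates on.
    """

    source: str
    annotation_class: str
    publication_id: Optional[str] = None

    def key(self) -> tuple:
        return (self.source, self.annotation_class, self.publication_id)


@dataclass
class DiseaseRecord:
    """One disease: opaque id, a main name, and any number of aliases.

    Alias comparison is case-insensitive; the main name never repeats among
    the aliases.
    """

    disease_id: str
    main_name: str
    aliases: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.disease_id or not self.main_name:
            raise ValidationError("disease_id and main_name must be non-empty")
        lowered = {a.lower() for a in self.aliases}
        if self.main_name.lower() in lowered:
            raise ValidationError(
                f"{self.disease_id}: main name {self.main_name!r} duplicated in aliases"
            )

    def all_names(self) -> list[tuple[str, str]]:
        """(name, via) pairs for matching; via is 'main_name' or 'alias'."""
        return [(self.main_name, "main_name")] + [(a, "alias") for a in self.aliases]


@dataclass
class Association:
    """A disease-gene pair with its deduplicated evidence list."""

    disease_id: str
    gene_symbol: str
    evidence: list[EvidenceItem]

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValidationError(
                f"association ({self.disease_id}, {self.gene_symbol}) has no evidence"
            )
        self.gene_symbol = self.gene_symbol.upper()
        seen: set[tuple] = set()
        deduped = []
        for ev in self.evidence:
            if ev.key() not in seen:
                seen.add(ev.key())
                deduped.append(ev)
        self.evidence = deduped

    @property
    def pair(self) -> tuple[str, str]:
        return (self.disease_id, self.gene_symbol)


@dataclass(frozen=True)
class GeneSet:
    """A named bag of genes (a biological pathway, SuperPath, or disease pathway)."""

    set_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.set_id!r} is empty")


@dataclass
class ScoreTable:
    """Base scores, source weights and every scoring/filtering constant.

    ``base_scores`` maps (source, annotation_class) to a positive base score;
    ``source_weights`` multiplies every evidence item of a source (default
    1.0).  ``elite_sources`` are the manually curated sources whose evidence
    can confer elite status; ``elite_threshold`` is the strict lower bound on
    the normalized D-G score of an elite edge.
    """

    base_scores: dict[tuple[str, str], float]
    source_weights: dict[str, float] = field(default_factory=dict)
    elite_sources: frozenset[str] = frozenset({"OMIM", "Orphanet", "ClinVar"})
    elite_threshold: float = 2.5
    pub_promiscuity_max: int = 5
    elite_bonus: float = 1.0
    per_source_mode: str = "sum"
    version: int = 1

    def __post_init__(self) -> None:
        for key, value in self.base_scores.items():
            if value <= 0:
                raise ValidationError(f"base score for {key} must be positive, got {value}")
        for src, w in self.source_weights.items():
            if w < 0:
                raise ValidationError(f"source weight for {src} must be non-negative, got {w}")
        if self.per_source_mode not in ("sum", "max"):
            raise ValidationError(f"per_source_mode must be 'sum' or 'max', got {self.per_source_mode!r}")
        if self.elite_bonus < 0:
            raise ValidationError("elite_bonus must be non-negative")
        if self.pub_promiscuity_max < 1:
            raise ValidationError("pub_promiscuity_max must be >= 1")

    def base_score(self, source: str, annotation_class: str) -> float:
        try:
            return self.base_scores[(source, annotation_class)]
        except KeyError:
            raise ValidationError(
                f"no base score configured for ({source!r}, {annotation_class!r})"
            ) from None

    def weight(self, source: str) -> float:
        return self.source_weights.get(source, 1.0)

    def knows(self, source: str, annotation_class: str) -> bool:
        return (source, annotation_class) in self.base_scores

    @classmethod
    def from_mapping(cls, data: Mapping) -> "ScoreTable":
        base = {}
        for source, classes in data.get("base_scores", {}).items():
            for ann, score in classes.items():
                base[(str(source), str(ann))] = float(score)
        if not base:
            raise ValidationError("score table defines no base scores")
        return cls(
            base_scores=base,
            source_weights={str(s): float(w) for s, w in (data.get("source_weights") or {}).items()},
            elite_sources=frozenset(data.get("elite_sources", ["OMIM", "Orphanet", "ClinVar"])),
            elite_threshold=float(data.get("elite_threshold", 2.5)),
            pub_promiscuity_max=int(data.get("pub_promiscuity_max", 5)),
            elite_bonus=float(data.get("elite_bonus", 1.0)),
            per_source_mode=str(data.get("per_source_mode", "sum")),
            version=int(data.get("version", 1)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ScoreTable":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise FormatError(f"{path}: score table must be a mapping")
        return cls.from_mapping(data)

    @classmethod
    def default(cls) -> "ScoreTable":
        """The shipped default table (versioned YAML packaged with malanet)."""
        ref = importlib.resources.files("malanet") / "data" / "score_table.yaml"
        return cls.from_mapping(yaml.safe_load(ref.read_text(encoding="utf-8")))


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")


def read_associations(
    path: str | Path,
    table: Optional[ScoreTable] = None,
    strict: bool = True,
) -> list[Association]:
    """Read an associations TSV and group rows into Association records.

    Rows sharing (disease_id, gene_symbol) merge into one association with a
    deduplicated evidence list; row order never affects the result.  When a
    ``table`` is given, rows with an unknown (source, annotation_class) raise
    a :class:`ValidationError` under ``strict`` mode and are dropped (with a
    warning on stderr) otherwise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ASSOCIATION_COLUMNS[:4], path)
    if "publication_id" not in df.columns:
        df["publication_id"] = ""

    offenders = []
    if table is not None:
        known = df.apply(lambda r: table.knows(r["source"], r["annotation_class"]), axis=1) \
            if len(df) else pd.Series(dtype=bool)
        if len(df) and not known.all():
            offenders = sorted(
                {(r["source"], r["annotation_class"])
                 for _, r in df[~known].iterrows()}
            )
            if strict:
                raise ValidationError(
                    "unknown (source, annotation_class) pairs: "
                    + ", ".join(f"({s}, {a})" for s, a in offenders)
                )
            import sys
            print(f"malanet: dropping {int((~known).sum())} rows with unknown "
                  f"score entries: {offenders}", file=sys.stderr)
            df = df[known]

    grouped: dict[tuple[str, str], list[EvidenceItem]] = {}
    for row in df.itertuples(index=False):
        key = (row.disease_id, row.gene_symbol.upper())
        ev = EvidenceItem(
            source=row.source,
            annotation_class=row.annotation_class,
            publication_id=row.publication_id or None,
        )
        grouped.setdefault(key, []).append(ev)
    return [
        Association(disease_id=d, gene_symbol=g, evidence=evs)
        for (d, g), evs in sorted(grouped.items())
    ]


def write_associations(associations: Iterable[Association], path: str | Path) -> None:
    rows = []
    for a in associations:
        for ev in a.evidence:
            rows.append((a.disease_id, a.gene_symbol, ev.source,
                         ev.annotation_class, ev.publication_id or ""))
    df = pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_diseases(path: str | Path) -> list[DiseaseRecord]:
    """Read the disease vocabulary TSV (aliases pipe-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, DISEASE_COLUMNS[:2], path)
    if "aliases" not in df.columns:
        df["aliases"] = ""
    records = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.disease_id in seen:
            raise ValidationError(f"{path}: duplicate disease_id {row.disease_id!r}")
        seen.add(row.disease_id)
        aliases = [a for a in row.aliases.split("|") if a]
        records.append(DiseaseRecord(row.disease_id, row.main_name, aliases))
    return records


def write_diseases(records: Iterable[DiseaseRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.disease_id, r.main_name, "|".join(r.aliases)) for r in records],
        columns=DISEASE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: one gene set per line, ``set_id<TAB>name<TAB>gene...``.

    Duplicate genes within a line collapse; a line with fewer than three
    fields is a format error reported with its line number.
    """
    sets: list[GeneSet] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            set_id, name, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: GMT line has no genes")
            sets.append(GeneSet(set_id=set_id, name=name, genes=frozenset(g.upper() for g in genes)))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.genes)]) + "\n")


def write_network(network, path: str | Path, format: str = "edge_tsv") -> None:
    """Export a scored network as ``edge_tsv`` (round-trippable) or ``graphml``.

    The edge TSV carries dg_raw, dg and gd to six decimal places, which the
    round-trip reader reproduces exactly.
    """
    edges = getattr(network, "edges", network)
    if format == "edge_tsv":
        rows = [(e.disease_id, e.gene_symbol,
                 f"{e.dg_raw:.6f}", f"{e.dg:.6f}", f"{e.gd:.6f}", int(e.elite))
                for e in edges]
        pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        import networkx as nx

        g = nx.Graph()
        for e in edges:
            d, gn = f"disease:{e.disease_id}", f"gene:{e.gene_symbol}"
            g.add_node(d, kind="disease", label=e.disease_id)
            g.add_node(gn, kind="gene", label=e.gene_symbol)
            g.add_edge(d, gn, dg_raw=float(e.dg_raw), dg=float(e.dg),
                       gd=float(e.gd), elite=bool(e.elite))
        nx.write_graphml(g, path)
    else:
        raise ValidationError(f"unknown network format {format!r} (use graphml or edge_tsv)")


def read_network_edges(path: str | Path):
    """Read an edge TSV written by :func:`write_network` back into ScoredEdges."""
    from .scoring import ScoredEdge

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, EDGE_COLUMNS, path)
    return [
        ScoredEdge(
            disease_id=row.disease_id,
            gene_symbol=row.gene_symbol,
            dg_raw=float(row.dg_raw),
            dg=float(row.dg),
            gd=float(row.gd),
            elite=bool(int(row.elite)),
        )
        for row in df.itertuples(index=False)
    ]
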