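"""Group-level presence bookkeeping and gene-list construction.

Species are organised into named groups with roles *lower*, *middle* and
*upper* relative to the evolutionary stage of interest.  Each reference
gene gets one presence count per group (the classic m/n/p/q columns when
the middle taxa are primitive mammals, birds and reptiles and the lower
non-reference taxon is fish).  Genes are then selected by a *metacondition*
— a small boolean expression over atoms ``present_in(group, k)``, true when
the gene is present in at least ``k`` species of the group (``k`` defaults
to 1) — and written as a deterministic table carrying coordinates, counts
and per-species ortholog ids.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .homology import GeneRecord
from .orthology import PresenceCall

__all__ = [
    "SpeciesGroup",
    "SpeciesGroupConfig",
    "presence_counts",
    "parse_metacondition",
    "eval_metacondition",
    "build_list",
    "GeneListRow",
]


@dataclass(frozen=True)
class SpeciesGroup:
    name: str
    species: Tuple[str, ...]
    role: str  # "lower" | "middle" | "upper"
    k: int = 1  # minimum presence for the group's default metacondition atom

    def __post_init__(self) -> None:
        if self.role not in ("lower", "middle", "upper"):
            raise ValueError(f"group {self.name!r}: unknown role {self.role!r}")
        if self.k < 0:
            raise ValueError(f"group {self.name!r}: k must be >= 0")


@dataclass(frozen=True)
class SpeciesGroupConfig:
    """Named, disjoint species groups plus the reference species."""

    groups: Tuple[SpeciesGroup, ...]
    reference: str

    def __post_init__(self) -> None:
        seen: Dict[str, str] = {}
        for g in self.groups:
            for sp in g.species:
                if sp in seen:
                    raise ValueError(
                        f"species {sp!r} in both {seen[sp]!r} and {g.name!r}")
                seen[sp] = g.name
        if self.reference not in seen:
            raise ValueError(
                f"reference species {self.reference!r} belongs to no group")

    def group(self, name: str) -> SpeciesGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(f"unknown species group {name!r}")

    def group_names(self) -> List[str]:
        return [g.name for g in self.groups]

    def non_reference_species(self) -> List[str]:
        out = []
        for g in self.groups:
            out.extend(sp for sp in g.species if sp != self.reference)
        return out

    def species_of_role(self, role: str, include_reference: bool = False) -> List[str]:
        out = []
        for g in self.groups:
            if g.role == role:
                out.extend(sp for sp in g.species
                           if include_reference or sp != self.reference)
        return out


def presence_counts(gene_id: str,
                    calls: Mapping[Tuple[str, str], PresenceCall],
                    config: SpeciesGroupConfig) -> Dict[str, int]:
    """Per-group count of species in which the gene is called present.

    The reference species is skipped (no self-call exists for it); every
    other configured species must have a call.
    """
    counts: Dict[str, int] = {}
    for g in config.groups:
        c = 0
        for sp in g.species:
            if sp == config.reference:
                continue
            call = calls.get((gene_id, sp))
            if call is None:
                raise KeyError(
                    f"no presence call for gene {gene_id!r} in species {sp!r}")
            if call.present:
                c += 1
        counts[g.name] = c
    return counts


# ---------------------------------------------------------------------------
# Metacondition expression language
# ---------------------------------------------------------------------------
#
# expr    := or
# or      := and ("or" and)*
# and     := not ("and" not)*
# not     := "not" not | atom
# atom    := "present_in" "(" NAME ["," INT] ")" | "(" expr ")" | "true" | "false"
#
# Case-insensitive keywords.  ``present_in(G, k)`` is true iff the gene's
# count for group G is at least k; k defaults to the group's configured
# minimum (1 unless overridden).

_TOKEN = re.compile(r"\s*(\(|\)|,|[A-Za-z_][A-Za-z0-9_\-]*|\d+)")


class Metacondition:
    """A parsed metacondition; call :meth:`evaluate` with per-group counts."""

    def __init__(self, ast, text: str):
        self._ast = ast
        self.text = text

    def evaluate(self, counts: Mapping[str, int],
                 config: Optional[SpeciesGroupConfig] = None) -> bool:
        return _eval_node(self._ast, counts, config)

    def __repr__(self) -> str:
        return f"Metacondition({self.text!r})"


def _tokenize(text: str) -> List[str]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise ValueError(f"metacondition: cannot tokenize {text[pos:]!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def parse_metacondition(text: str) -> Metacondition:
    """Parse a metacondition expression.

    Example: ``present_in(fish, 1) and not present_in(placentals)``.
    """
    tokens = _tokenize(text)
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take(expected: Optional[str] = None) -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError(f"metacondition {text!r}: unexpected end")
        tok = tokens[pos]
        if expected is not None and tok != expected:
            raise ValueError(
                f"metacondition {text!r}: expected {expected!r}, got {tok!r}")
        pos += 1
        return tok

    def parse_or():
        node = parse_and()
        while peek() is not None and peek().lower() == "or":
            take()
            node = ("or", node, parse_and())
        return node

    def parse_and():
        node = parse_not()
        while peek() is not None and peek().lower() == "and":
            take()
            node = ("and", node, parse_not())
        return node

    def parse_not():
        if peek() is not None and peek().lower() == "not":
            take()
            return ("not", parse_not())
        return parse_atom()

    def parse_atom():
        tok = peek()
        if tok == "(":
            take()
            node = parse_or()
            take(")")
            return node
        if tok is not None and tok.lower() in ("true", "false"):
            take()
            return ("const", tok.lower() == "true")
        if tok is not None and tok.lower() == "present_in":
            take()
            take("(")
            group = take()
            k = None
            if peek() == ",":
                take()
                k = int(take())
            take(")")
            return ("present_in", group, k)
        raise ValueError(f"metacondition {text!r}: unexpected token {tok!r}")

    ast = parse_or()
    if pos != len(tokens):
        raise ValueError(f"metacondition {text!r}: trailing tokens {tokens[pos:]}")
    return Metacondition(ast, text)


def _eval_node(node, counts: Mapping[str, int],
               config: Optional[SpeciesGroupConfig]) -> bool:
    op = node[0]
    if op == "const":
        return node[1]
    if op == "not":
        return not _eval_node(node[1], counts, config)
    if op == "and":
        return _eval_node(node[1], counts, config) and _eval_node(node[2], counts, config)
    if op == "or":
        return _eval_node(node[1], counts, config) or _eval_node(node[2], counts, config)
    if op == "present_in":
        group, k = node[1], node[2]
        if group not in counts:
            raise KeyError(f"metacondition references unknown group {group!r}")
        if k is None:
            k = config.group(group).k if config is not None else 1
        return counts[group] >= k
    raise AssertionError(f"bad AST node {node!r}")


def eval_metacondition(expr: str | Metacondition,
                       counts: Mapping[str, int],
                       config: Optional[SpeciesGroupConfig] = None) -> bool:
    """Evaluate a metacondition (text or pre-parsed) on per-group counts."""
    if isinstance(expr, str):
        expr = parse_metacondition(expr)
    return expr.evaluate(counts, config)


# ---------------------------------------------------------------------------
# Gene-list construction
# ---------------------------------------------------------------------------

@dataclass
class GeneListRow:
    """One selected reference gene with its counts and per-species orthologs."""

    gene: GeneRecord
    counts: Dict[str, int]
    orthologs: Dict[str, str]  # species -> ortholog gene id ('' when absent)


def build_list(ref_genes: Sequence[GeneRecord],
               expr: str | Metacondition,
               calls: Mapping[Tuple[str, str], PresenceCall],
               config: SpeciesGroupConfig) -> List[GeneListRow]:
    """Select reference genes satisfying the metacondition.

    Rows are ordered by (seq_id, start, gene_id) so a rerun on identical
    inputs reproduces the list byte-for-byte.
    """
    if isinstance(expr, str):
        expr = parse_metacondition(expr)
    rows: List[GeneListRow] = []
    for gene in sorted(ref_genes, key=lambda g: (g.seq_id, g.start, g.gene_id)):
        counts = presence_counts(gene.gene_id, calls, config)
        if not expr.evaluate(counts, config):
            continue
        orthologs: Dict[str, str] = {}
        for sp in config.non_reference_species():
            call = calls[(gene.gene_id, sp)]
            orthologs[sp] = call.ortholog or ""
        rows.append(GeneListRow(gene=gene, counts=counts, orthologs=orthologs))
    return rows


def write_gene_list(rows: Sequence[GeneListRow], config: SpeciesGroupConfig,
                    path: str | Path) -> None:
    """Write a gene list as TSV: coordinates, per-group counts, then one
    ortholog-id column per non-reference species."""
    group_names = config.group_names()
    species = config.non_reference_species()
    header = (["gene_id", "seq_id", "start", "end", "strand"]
              + [f"count_{g}" for g in group_names] + species)
    with Path(path).open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            g = row.gene
            fields = [g.gene_id, g.seq_id, str(g.start), str(g.end), g.strand]
            fields += [str(row.counts[name]) for name in group_names]
            fields += [row.orthologs.get(sp, "") for sp in species]
            fh.write("\t".join(fields) + "\n")
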