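"""End-to-end orchestration of the screen.

Stages: protein score matrix → homolog table → presence calls → loss list
(list-1) → DE filter (list-2) → intersection (list-3) → middle-taxa-absent
subset (list-4) → three-species filter (final list).  Every stage's output
is a pure function of the inputs and configuration; when an output
directory is given, each stage is written as TSV/JSON together with a run
manifest (config snapshot, checksums, version) so a rerun on identical
inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .de_integration import DERecord, filter_de, intersect_lists
from .homology import GeneRecord, HomologTable, build_homolog_table
from .orthology import GenomeIndex, Parameters, PresenceCall, call_presence_matrix
from .scores import ProteinRecord, build_protein_matrix, symmetrize_matrix
from .screening import (GeneListRow, SpeciesGroupConfig, build_list,
                        parse_metacondition, presence_counts, write_gene_list)
from .three_species import DEFAULT_RADII, ThreeSpeciesFlags, three_species_flags, apply_final_filter

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "load_config_yaml"]


def load_config_yaml(path: str | Path) -> "PipelineConfig":
    """Build a :class:`PipelineConfig` from a YAML run configuration.

    Expected shape::

        reference: ref
        groups:
          - {name: fish, role: lower, species: [fish1, fish2], k: 1}
          - {name: placentals, role: upper, species: [plac1, plac2]}
        params: {u: 3, radius: 5000000, lam: 0.0}
        list1_condition: present_in(fish) and not present_in(placentals)
        fdr_max: 0.01
        radii: [1000000, 2000000, 5000000]
    """
    import yaml

    from .screening import SpeciesGroup

    raw = yaml.safe_load(Path(path).read_text())
    groups = SpeciesGroupConfig(
        groups=tuple(SpeciesGroup(name=g["name"], role=g["role"],
                                  species=tuple(g["species"]),
                                  k=int(g.get("k", 1)))
                     for g in raw["groups"]),
        reference=raw["reference"])
    pkw = dict(raw.get("params", {}))
    if "radius_by_species" in pkw:
        pkw["radius_by_species"] = dict(pkw["radius_by_species"])
    params = Parameters(**pkw)
    kwargs = {}
    for key in ("list1_condition", "list4_condition", "fdr_max", "theta_min",
                "e_value_cut", "normalization"):
        if key in raw:
            kwargs[key] = raw[key]
    if "radii" in raw:
        kwargs["radii"] = tuple(int(r) for r in raw["radii"])
    return PipelineConfig(groups=groups, params=params, **kwargs)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the screen needs beyond the input data itself."""

    groups: SpeciesGroupConfig
    params: Parameters = field(default_factory=Parameters)
    list1_condition: Optional[str] = None  # default: lower-present and upper-absent
    list4_condition: Optional[str] = None  # default: absent from all middle groups
    fdr_max: float = 0.01
    theta_min: float = 0.0
    radii: Tuple[int, ...] = DEFAULT_RADII
    e_value_cut: float = 0.1
    normalization: str = "mean"

    def resolved_list1_condition(self) -> str:
        if self.list1_condition is not None:
            return self.list1_condition
        ref_group = next(g.name for g in self.groups.groups
                         if self.groups.reference in g.species)
        lower = [g.name for g in self.groups.groups
                 if g.role == "lower" and g.name != ref_group]
        upper = [g.name for g in self.groups.groups if g.role == "upper"]
        if not lower or not upper:
            raise ValueError("cannot derive a list-1 condition: need at least "
                             "one non-reference lower group and one upper group")
        present = " or ".join(f"present_in({g})" for g in lower)
        absent = " or ".join(f"present_in({g}, 1)" for g in upper)
        return f"({present}) and not ({absent})"

    def resolved_list4_condition(self) -> str:
        if self.list4_condition is not None:
            return self.list4_condition
        middle = [g.name for g in self.groups.groups if g.role == "middle"]
        if not middle:
            return "true"
        return " and ".join(f"not present_in({m}, 1)" for m in middle)


@dataclass
class PipelineResult:
    """All intermediates and final outputs of one run."""

    table: HomologTable
    calls: Dict[Tuple[str, str], PresenceCall]
    list1: List[GeneListRow]
    list2: Dict[str, float]  # DE gene -> logFC
    list3: List[Tuple[str, float]]  # (gene, logFC), descending logFC
    list4: List[Tuple[str, float]]
    flags: Dict[str, ThreeSpeciesFlags]
    final: List[Tuple[str, float]]
    n_up: int
    n_down: int
    manifest: Optional[dict] = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(proteins: Sequence[ProteinRecord],
                 annotations: Mapping[str, Sequence[GeneRecord]],
                 de_records: Sequence[DERecord],
                 config: PipelineConfig,
                 outdir: Optional[str | Path] = None,
                 score_table: Optional[str | Path] = None,
                 ) -> PipelineResult:
    """Run the full screen.

    ``score_table`` switches the score stage to a precomputed raw-score TSV
    instead of the built-in aligner.  With ``outdir`` set, stage outputs and
    a run manifest are written there.
    """
    groups = config.groups
    params = config.params
    ref = groups.reference
    configured = {sp for g in groups.groups for sp in g.species}
    if ref not in annotations:
        raise ValueError(f"no annotations for reference species {ref!r}")
    missing = configured - set(annotations)
    if missing:
        raise ValueError(f"no annotations for configured species {sorted(missing)}")

    # stage 1-2: scores and homolog table
    source = "precomputed" if score_table is not None else "aligner"
    V = build_protein_matrix(proteins, e_value_cut=config.e_value_cut,
                             source=source, score_table=score_table)
    symmetrize_matrix(V, normalization=config.normalization)
    all_genes = [g for sp in sorted(annotations) for g in annotations[sp]]
    table = build_homolog_table(all_genes, V, u=params.u,
                                weight_min=params.weight_min,
                                e_value_max=params.e_value_max)

    # stage 3: presence calls
    index = GenomeIndex(all_genes)
    ref_genes = sorted(annotations[ref], key=lambda g: (g.seq_id, g.start, g.gene_id))
    species = sorted(configured - {ref})
    calls = call_presence_matrix(ref_genes, species, table, index, params)

    # stage 4: list-1
    list1_expr = parse_metacondition(config.resolved_list1_condition())
    list1 = build_list(ref_genes, list1_expr, calls, groups)

    # stage 5: list-2 (DE filter)
    list2 = filter_de(de_records, fdr_max=config.fdr_max,
                      theta_min=config.theta_min)

    # stage 6: list-3 (intersection)
    list3, _up3, _down3 = intersect_lists([r.gene.gene_id for r in list1], list2)

    # stage 7: list-4 (middle-taxa metacondition on list-3 genes)
    list4_expr = parse_metacondition(config.resolved_list4_condition())
    list4 = []
    for gene_id, logfc in list3:
        counts = presence_counts(gene_id, calls, groups)
        if list4_expr.evaluate(counts, groups):
            list4.append((gene_id, logfc))

    # stage 8: three-species filter -> final list
    fish_species = groups.species_of_role("lower")
    upper_species = groups.species_of_role("upper")
    gene_by_id = {g.gene_id: g for g in ref_genes}
    flags: Dict[str, ThreeSpeciesFlags] = {}
    for gene_id, _fc in list4:
        flags[gene_id] = three_species_flags(
            gene_by_id[gene_id], fish_species, upper_species, table, index,
            params, radii=config.radii)
    kept = apply_final_filter([gene_by_id[g] for g, _ in list4], flags)
    kept_ids = {g.gene_id for g in kept}
    final = [(g, fc) for g, fc in list4 if g in kept_ids]
    n_up = sum(1 for _g, fc in final if fc > 0)
    n_down = sum(1 for _g, fc in final if fc < 0)

    result = PipelineResult(table=table, calls=calls, list1=list1,
                            list2=list2, list3=list3, list4=list4,
                            flags=flags, final=final, n_up=n_up, n_down=n_down)
    if outdir is not None:
        result.manifest = _write_outputs(result, config, Path(outdir))
    return result


def _write_list(path: Path, rows: Sequence[Tuple[str, float]]) -> None:
    with path.open("w") as fh:
        fh.write("gene_id\tlogFC\n")
        for g, fc in rows:
            fh.write(f"{g}\t{fc:.6g}\n")


def _write_outputs(result: PipelineResult, config: PipelineConfig,
                   outdir: Path) -> dict:
    from . import __version__
    from .io import write_evidence_json, write_presence_matrix

    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "homolog_table": outdir / "homolog_table.tsv",
        "presence_matrix": outdir / "presence_matrix.tsv",
        "evidence": outdir / "evidence.json",
        "list1": outdir / "list1.tsv",
        "list2": outdir / "list2.tsv",
        "list3": outdir / "list3.tsv",
        "list4": outdir / "list4.tsv",
        "three_species_flags": outdir / "three_species_flags.tsv",
        "final_list": outdir / "final_list.tsv",
    }
    result.table.to_tsv(paths["homolog_table"])
    write_presence_matrix(result.calls, paths["presence_matrix"])
    write_evidence_json(result.calls, paths["evidence"])
    write_gene_list(result.list1, config.groups, paths["list1"])
    with paths["list2"].open("w") as fh:
        fh.write("gene_id\tlogFC\n")
        for g in sorted(result.list2):
            fh.write(f"{g}\t{result.list2[g]:.6g}\n")
    _write_list(paths["list3"], result.list3)
    _write_list(paths["list4"], result.list4)
    with paths["three_species_flags"].open("w") as fh:
        radii = config.radii
        fh.write("gene_id\t" + "\t".join(f"flag_r{r}" for r in radii) + "\n")
        for g in sorted(result.flags):
            f = result.flags[g]
            fh.write(g + "\t" + "\t".join(str(x) for x in f.flags) + "\n")
    _write_list(paths["final_list"], result.final)

    manifest = {
        "tool_version": __version__,
        "generated_utc": datetime.now(timezone.utc).isoformat(),
        "config": {
            "reference": config.groups.reference,
            "groups": [dataclasses.asdict(g) for g in config.groups.groups],
            "params": dataclasses.asdict(config.params),
            "list1_condition": config.resolved_list1_condition(),
            "list4_condition": config.resolved_list4_condition(),
            "fdr_max": config.fdr_max,
            "theta_min": config.theta_min,
            "radii": list(config.radii),
            "e_value_cut": config.e_value_cut,
            "normalization": config.normalization,
        },
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)}
                    for name, p in paths.items()},
        "summary": {
            "list1": len(result.list1), "list2": len(result.list2),
            "list3": len(result.list3), "list4": len(result.list4),
            "final": len(result.final), "up": result.n_up,
            "down": result.n_down,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
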