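"""Plain-text I/O for every pipeline artifact.

All formats are tab-separated text so that artifacts diff cleanly and
round-trip losslessly (floats at 6 significant digits):

* interactome / network edge lists: ``node_a  node_b  weight  origin``
* GCT-like expression panels: a ``#condition`` header line, then gene rows
  with control and treated replicate columns
* GMT gene sets: ``set_name  description  gene1  gene2 ...``
* simple label tables (regnet, targets, localization, MoA, sensitivity)
* terminal sets: ``protein  prize  source``
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import CohortBundle, CohortConfig
from .interactome import REFERENCE
from .terminals import ExpressionPanel, TerminalSet

__all__ = [
    "write_edge_list",
    "read_edge_list",
    "write_gmt",
    "read_gmt",
    "write_panel",
    "read_panel",
    "write_terminal_set",
    "read_terminal_set",
    "write_cohort",
    "read_cohort",
    "write_network",
]

_FLOAT_FMT = "%.6g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def write_edge_list(g: nx.Graph, path: Path | str) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("node_a\tnode_b\tweight\torigin\n")
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            d = g.edges[u, v]
            fh.write(f"{u}\t{v}\t{_fmt(d['weight'])}\t{d.get('origin', REFERENCE)}\n")


def read_edge_list(path: Path | str) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(row.node_a, row.node_b, weight=float(row.weight), origin=row.origin)
    return g


def write_gmt(gene_sets: Mapping[str, set[str]], path: Path | str, description: str = "synthetic") -> None:
    with Path(path).open("w") as fh:
        for name in sorted(gene_sets):
            members = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_gmt(path: Path | str) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_panel(panel: ExpressionPanel, path: Path | str) -> None:
    cl, drug = panel.condition
    k_c, k_t = panel.control.shape[1], panel.treated.shape[1]
    cols = [f"control_{i+1}" for i in range(k_c)] + [f"treated_{i+1}" for i in range(k_t)]
    with Path(path).open("w") as fh:
        fh.write(f"#condition\t{cl}\t{drug}\n")
        fh.write("gene\t" + "\t".join(cols) + "\n")
        for i, g in enumerate(panel.genes):
            vals = [_fmt(x) for x in panel.control[i]] + [_fmt(x) for x in panel.treated[i]]
            fh.write(g + "\t" + "\t".join(vals) + "\n")


def read_panel(path: Path | str) -> ExpressionPanel:
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    if header[0] != "#condition":
        raise ValueError(f"{path}: missing #condition header line")
    cl, drug = header[1], header[2]
    cols = lines[1].split("\t")[1:]
    n_c = sum(c.startswith("control_") for c in cols)
    genes, rows = [], []
    for line in lines[2:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        genes.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    arr = np.array(rows, dtype=float)
    return ExpressionPanel(
        genes=genes, control=arr[:, :n_c], treated=arr[:, n_c:], condition=(cl, drug)
    )


def write_terminal_set(ts: TerminalSet, path: Path | str) -> None:
    with Path(path).open("w") as fh:
        fh.write("protein\tprize\tsource\n")
        for p in sorted(ts.entries):
            prize, src = ts.entries[p]
            fh.write(f"{p}\t{_fmt(prize)}\t{src}\n")


def read_terminal_set(path: Path | str, condition: str = "") -> TerminalSet:
    df = pd.read_csv(path, sep="\t", dtype={"protein": str})
    entries = {r.protein: (float(r.prize), r.source) for r in df.itertuples(index=False)}
    return TerminalSet(entries, condition=condition)


def write_network(net, path: Path | str) -> None:
    """Edge list + node-attribute table for one reconstructed network."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("node_a\tnode_b\tweight\torigin\n")
        for u, v, w, origin in net.edges:
            fh.write(f"{u}\t{v}\t{_fmt(w)}\t{origin}\n")
    nodes_path = path.with_name(path.stem + ".nodes.tsv")
    with nodes_path.open("w") as fh:
        fh.write("protein\trole\n")
        for p in sorted(net.nodes):
            fh.write(f"{p}\t{net.nodes[p]}\n")


def write_cohort(bundle: CohortBundle, directory: Path | str) -> dict[str, str]:
    """Write the full synthetic study; returns the file manifest.

    One expression and one phospho table per (cell line, drug) condition,
    plus the interactome, regulatory network, annotations and labels. The
    manifest is also saved as ``manifest.json`` in the directory.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def register(key: str, name: str) -> Path:
        manifest[key] = name
        return d / name

    try:
        write_edge_list(bundle.interactome, register("interactome", "interactome.tsv"))
        write_gmt(bundle.gene_sets, register("gene_sets", "gene_sets.gmt"))
        for (cl, drug), panel in sorted(bundle.panels.items()):
            write_panel(panel, register(f"expr:{cl}:{drug}", f"expr_{cl}_{drug}.tsv"))
        for (cl, drug), table in sorted(bundle.phospho_tables.items()):
            table.to_csv(
                register(f"phospho:{cl}:{drug}", f"phospho_{cl}_{drug}.tsv"),
                sep="\t", index=False, float_format=_FLOAT_FMT,
            )
        _write_pairs(
            register("regnet", "regnet.tsv"), "tf\ttarget",
            [(tf, t) for tf in sorted(bundle.regnet) for t in sorted(bundle.regnet[tf])],
        )
        _write_pairs(
            register("drug_targets", "drug_targets.tsv"), "drug\ttarget",
            [(dr, t) for dr in sorted(bundle.drug_targets) for t in sorted(bundle.drug_targets[dr])],
        )
        _write_pairs(
            register("localization", "localization.tsv"), "protein\tlocation",
            [(p, loc) for p in sorted(bundle.localization) for loc in sorted(bundle.localization[p])],
        )
        _write_pairs(
            register("moa_labels", "moa_labels.tsv"), "drug\tmoa",
            sorted(bundle.moa_labels.items()),
        )
        with register("driver_genes", "driver_genes.tsv").open("w") as fh:
            fh.write("protein\n")
            fh.writelines(f"{p}\n" for p in sorted(bundle.driver_genes))
        _write_pairs(
            register("sensitivity", "sensitivity.tsv"), "cell_line\tdrug\tz",
            [(cl, dr, _fmt(z)) for (cl, dr), z in sorted(bundle.sensitivity.items())],
        )
        _write_pairs(
            register("truth", "truth.tsv"), "drug\tmodules",
            [(dr, ",".join(mods)) for dr, mods in sorted(bundle.truth.items())],
        )
        with register("config", "config.json").open("w") as fh:
            cfg = {**bundle.config.__dict__}
            cfg["baseline_range"] = list(cfg["baseline_range"])
            json.dump(cfg, fh, indent=1)
        with (d / "manifest.json").open("w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    except OSError as exc:
        raise OSError(f"failed writing cohort under {d}: {exc}") from exc
    return manifest


def _write_pairs(path: Path, header: str, rows) -> None:
    with path.open("w") as fh:
        fh.write(header + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_cohort(directory: Path | str) -> CohortBundle:
    """Read a cohort written by :func:`write_cohort` back into memory."""
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    cfg = json.loads((d / manifest["config"]).read_text())
    cfg["baseline_range"] = tuple(cfg["baseline_range"])
    config = CohortConfig(**cfg)

    interactome = read_edge_list(d / manifest["interactome"])
    gene_sets = read_gmt(d / manifest["gene_sets"])
    panels, phospho = {}, {}
    for key, name in manifest.items():
        if key.startswith("expr:"):
            _, cl, drug = key.split(":")
            panels[(cl, drug)] = read_panel(d / name)
        elif key.startswith("phospho:"):
            _, cl, drug = key.split(":")
            phospho[(cl, drug)] = pd.read_csv(d / name, sep="\t", dtype={"protein": str})

    regnet: dict[str, set[str]] = {}
    for r in pd.read_csv(d / manifest["regnet"], sep="\t", dtype=str).itertuples(index=False):
        regnet.setdefault(r.tf, set()).add(r.target)
    drug_targets: dict[str, set[str]] = {}
    for r in pd.read_csv(d / manifest["drug_targets"], sep="\t", dtype=str).itertuples(index=False):
        drug_targets.setdefault(r.drug, set()).add(r.target)
    localization: dict[str, set[str]] = {}
    for r in pd.read_csv(d / manifest["localization"], sep="\t", dtype=str).itertuples(index=False):
        localization.setdefault(r.protein, set()).add(r.location)
    moa = dict(
        pd.read_csv(d / manifest["moa_labels"], sep="\t", dtype=str).itertuples(index=False)
    )
    drivers = set(pd.read_csv(d / manifest["driver_genes"], sep="\t", dtype=str)["protein"])
    sens = {
        (r.cell_line, r.drug): float(r.z)
        for r in pd.read_csv(
            d / manifest["sensitivity"], sep="\t", dtype={"cell_line": str, "drug": str}
        ).itertuples(index=False)
    }
    truth = {
        r.drug: r.modules.split(",")
        for r in pd.read_csv(d / manifest["truth"], sep="\t", dtype=str).itertuples(index=False)
    }
    return CohortBundle(
        config=config,
        interactome=interactome,
        panels=panels,
        phospho_tables=phospho,
        regnet=regnet,
        drug_targets=drug_targets,
        localization=localization,
        gene_sets=gene_sets,
        moa_labels=moa,
        driver_genes=drivers,
        sensitivity=sens,
        truth=truth,
    )
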