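"""Writers for the design deliverables.

A run produces a results directory holding three tab-separated text files
(the bench-facing contract), a Tm scatter plot, and a machine-readable
``design.json``:

* ``all_sense_fragments.txt`` — the method-A oligo set;
* ``sense_antisense_fragments.txt`` — the method-B oligo set;
* ``gene_primers.txt`` — the full-length gene primer pair;
* ``block_primers.txt`` — per-block primer pairs (when blocks are planned).

Fragment tables carry seven columns: fragment sequence (on the ordering
strand), junction overlap sequence (always sense strand), its Tm, its
deviation from the design Tm_mean, fragment_len, overlap_len and the
1-based inclusive start_pos-end_pos on the gene. Temperatures are printed
to two decimals. The last fragment has no right junction, so its overlap
columns are empty.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .assembly import BlockPlan, OrderedOligo
from .design import DesignResult
from .sequences import GeneSequence

__all__ = [
    "FRAGMENT_COLUMNS",
    "write_design_tables",
    "write_block_primers",
    "write_design_json",
    "read_fragment_table",
    "plot_tm_scatter",
]

FRAGMENT_COLUMNS = ("fragment", "overlap", "Tm", "Tm-Tm_mean",
                    "fragment_len", "overlap_len", "start_pos-end_pos")

_FRAGMENT_FILES = {"A": "all_sense_fragments.txt",
                   "B": "sense_antisense_fragments.txt"}


def _fragment_rows(design: DesignResult,
                   oligos: Sequence[OrderedOligo]) -> list[list[str]]:
    rows = []
    for frag, oligo in zip(design.fragments, oligos):
        j = frag.right_overlap
        rows.append([
            oligo.seq,
            j.seq_sense if j else "",
            f"{j.tm:.2f}" if j else "",
            f"{j.tm_deviation:.2f}" if j else "",
            str(frag.length),
            str(j.length) if j else "",
            f"{frag.start_pos}-{frag.end_pos}",
        ])
    return rows


def _write_tsv(path: Path, header: Sequence[str],
               rows: Sequence[Sequence[str]]) -> None:
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def write_design_tables(design: DesignResult,
                        oligos_a: Sequence[OrderedOligo],
                        oligos_b: Sequence[OrderedOligo],
                        out_dir: str | Path) -> dict[str, Path]:
    """Write the three bench text files; returns name -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for oligos, fname in ((oligos_a, _FRAGMENT_FILES["A"]),
                          (oligos_b, _FRAGMENT_FILES["B"])):
        path = out_dir / fname
        _write_tsv(path, FRAGMENT_COLUMNS, _fragment_rows(design, oligos))
        paths[fname] = path
    if design.primers is None:
        raise ValueError("design has no gene primers to write")
    p = design.primers
    path = out_dir / "gene_primers.txt"
    _write_tsv(path, ("primer", "Tm", "Tm-Tm_mean"), [
        [p.sense_primer, f"{p.tm_sense:.2f}", f"{p.tm_deviation_sense:.2f}"],
        [p.antisense_primer, f"{p.tm_antisense:.2f}",
         f"{p.tm_deviation_antisense:.2f}"],
    ])
    paths["gene_primers.txt"] = path
    return paths


def write_block_primers(plan: BlockPlan, out_dir: str | Path) -> Path:
    """Tab-separated per-block primer pairs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, ((first, last), pair) in enumerate(
            zip(plan.block_ranges, plan.primer_pairs), start=1):
        rows.append([str(k), f"{first}-{last}",
                     pair.forward, f"{pair.tm_forward:.2f}",
                     pair.reverse, f"{pair.tm_reverse:.2f}"])
    path = out_dir / "block_primers.txt"
    _write_tsv(path, ("block", "fragments", "forward_primer", "Tm_forward",
                      "reverse_primer", "Tm_reverse"), rows)
    return path


def read_fragment_table(path: str | Path) -> list[dict[str, str]]:
    """Parse a fragment table back into a list of column dicts.

    Round-trip helper: rebuilding fragments from these rows must reproduce
    the design they were written from.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header = lines[0].split("\t")
    if tuple(header) != FRAGMENT_COLUMNS:
        raise ValueError(f"{path}: unexpected header {header}")
    rows = []
    for line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ValueError(f"{path}: ragged row {fields}")
        rows.append(dict(zip(header, fields)))
    return rows


def design_to_dict(design: DesignResult,
                   plan: BlockPlan | None = None) -> dict:
    """JSON-serializable view of a full design."""
    out = {
        "gene": {"id": design.gene.id, "length": design.gene.length,
                 "seq": design.gene.seq},
        "params": dataclasses.asdict(design.params),
        "tm_set_chosen": design.tm_set_chosen,
        "tm_mean": design.tm_mean,
        "tm_dev_max": design.tm_dev_max,
        "fragments": [
            {
                "index": f.index,
                "seq_sense": f.seq_sense,
                "start_pos": f.start_pos,
                "end_pos": f.end_pos,
                "right_overlap": dataclasses.asdict(f.right_overlap)
                if f.right_overlap else None,
            }
            for f in design.fragments
        ],
        "gene_primers": dataclasses.asdict(design.primers)
        if design.primers else None,
    }
    if plan is not None:
        out["blocks"] = {
            "sizes": plan.block_sizes,
            "ranges": plan.block_ranges,
            "primer_pairs": [dataclasses.asdict(p)
                             for p in plan.primer_pairs],
        }
    return out


def write_design_json(design: DesignResult, out_dir: str | Path,
                      plan: BlockPlan | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "design.json"
    path.write_text(json.dumps(design_to_dict(design, plan), indent=2) + "\n")
    return path


def plot_tm_scatter(design: DesignResult, path: str | Path) -> Path:
    """Scatter of junction Tm by junction index, with a horizontal line at
    the design Tm_mean. Written to file (Agg backend; no display needed)."""
    junctions = design.junctions
    if not junctions:
        raise ValueError("design has no junctions to plot")
    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.scatter(range(1, len(junctions) + 1), [j.tm for j in junctions],
               color="tab:blue", zorder=3, label="junction Tm")
    ax.axhline(design.tm_mean, color="tab:red", linewidth=1,
               label=f"Tm_mean = {design.tm_mean:.2f} degC")
    ax.set_xlabel("junction index")
    ax.set_ylabel("Tm (degC)")
    ax.set_title(f"{design.gene.id}: overlap Tm "
                 f"(Tm_set = {design.tm_set_chosen} degC)")
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata={"Software": None})
    plt.close(fig)
    return path
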