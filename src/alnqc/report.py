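"""Serialisation of QC summaries: tab-separated text, XML (validated
against a shipped schema), diagnostic plots, and a static multi-sample
HTML site.

Every number written to any format is derived from the accumulator via the
metrics/gcbias modules; text and XML are byte-identical across runs given
identical inputs.  Plots are rendered with matplotlib and the plotted
arrays are additionally exported as TSV so figure content is testable
without pixel comparison.
"""

from __future__ import annotations

import html
import math
import os
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import __version__
from .engine import QcAccumulator
from .gcbias import GcBiasCurve, GcWindowSchema, gc_bias_score, gc_curve
from .metrics import (
    CoverageSummary,
    CycleTable,
    InsertSizeSummary,
    QualityConcordanceTable,
    concordance_table,
    coverage_summary,
    cycle_table,
    insert_summary,
    quality_mse,
)

_FLOAT_FMT = "%.4f"


def _fmt(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "nan"
    return _FLOAT_FMT % x


@dataclass
class MetricsReport:
    """Derived tables and scalar summaries for one sample, ready for
    serialisation and plotting."""

    label: str
    concordance: QualityConcordanceTable
    cycles: CycleTable
    gc: GcBiasCurve | None
    gc_bias_score: float
    inserts: dict[str, InsertSizeSummary]
    coverage: CoverageSummary
    quality_mse: float
    provenance: dict[str, str] = field(default_factory=dict)


def compile_report(
    acc: QcAccumulator,
    schema: GcWindowSchema | None,
    label: str,
    analysis_span: int,
    provenance: dict[str, str] | None = None,
) -> MetricsReport:
    """Derive all tables and scalars from one accumulator.

    Degenerate inputs stay serialisable: with no aligned bases the GC curve
    is absent and the scalar summaries are NaN.
    """
    conc = concordance_table(acc)
    try:
        mse = quality_mse(conc)
    except ValueError:
        mse = float("nan")
    curve = None
    score = float("nan")
    if schema is not None and acc.total_aligned_bases > 0:
        try:
            curve = gc_curve(acc, schema)
            score = gc_bias_score(curve)
        except ValueError:
            curve = None
    prov = {"tool_version": __version__, "sample": label}
    prov.update(provenance or {})
    return MetricsReport(
        label=label,
        concordance=conc,
        cycles=cycle_table(acc),
        gc=curve,
        gc_bias_score=score,
        inserts=insert_summary(acc),
        coverage=coverage_summary(acc, analysis_span),
        quality_mse=mse,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# text

def write_text(report: MetricsReport, path: str | os.PathLike) -> None:
    """Tab-separated sections with fixed headers; floats at 4 decimals;
    byte-identical across runs on identical inputs."""
    cov = report.coverage
    lines: list[str] = ["# alnqc summary\tv" + __version__]
    lines.append("[provenance]")
    for k in sorted(report.provenance):
        lines.append(f"{k}\t{report.provenance[k]}")
    lines.append("[summary]")
    for k, v in _summary_scalars(report).items():
        lines.append(f"{k}\t{v}")
    lines.append("[quality_concordance]")
    lines.append("reported_q\tn_matches\tn_mismatches\tn_bases\tempirical_q\tcensored")
    for r in report.concordance.frame.itertuples(index=False):
        lines.append(
            f"{r.reported_q}\t{r.n_matches}\t{r.n_mismatches}\t{r.n_bases}"
            f"\t{_fmt(r.empirical_q)}\t{int(r.censored)}"
        )
    lines.append("[cycles]")
    lines.append(
        "cycle\tn_bases\tn_matches\tn_mismatches\tempirical_q\tcensored"
        "\tmean_reported_q\tfrac_A\tfrac_C\tfrac_G\tfrac_T\tfrac_N"
    )
    for r in report.cycles.frame.itertuples(index=False):
        lines.append(
            f"{r.cycle}\t{r.n_bases}\t{r.n_matches}\t{r.n_mismatches}"
            f"\t{_fmt(r.empirical_q)}\t{int(r.censored)}\t{_fmt(r.mean_reported_q)}"
            f"\t{_fmt(r.frac_A)}\t{_fmt(r.frac_C)}\t{_fmt(r.frac_G)}"
            f"\t{_fmt(r.frac_T)}\t{_fmt(r.frac_N)}"
        )
    lines.append("[gc_bias]")
    lines.append("gc_bin\tn_windows\tweight\tmean_depth\tnormalized_depth")
    if report.gc is not None:
        for r in report.gc.to_frame().itertuples(index=False):
            lines.append(
                f"{r.gc_bin}\t{r.n_windows}\t{_fmt(r.weight)}"
                f"\t{_fmt(r.mean_depth)}\t{_fmt(r.normalized_depth)}"
            )
    lines.append("[insert_summary]")
    lines.append("read_group\tn_pairs\tmode\tmean\tmedian\tsd\toverflow_fraction")
    for rg, s in sorted(report.inserts.items()):
        lines.append(
            f"{rg}\t{s.n_pairs}\t{s.mode}\t{_fmt(s.mean)}\t{_fmt(s.median)}"
            f"\t{_fmt(s.sd)}\t{_fmt(s.overflow_fraction)}"
        )
    lines.append("[insert_histogram]")
    lines.append("read_group\tinsert_size\tcount")
    for rg, s in sorted(report.inserts.items()):
        for size in np.nonzero(s.histogram)[0]:
            name = "overflow" if size == s.cap + 1 else str(int(size))
            lines.append(f"{rg}\t{name}\t{int(s.histogram[size])}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _summary_scalars(report: MetricsReport) -> dict[str, str]:
    cov = report.coverage
    return {
        "quality_mse": _fmt(report.quality_mse),
        "gc_bias_score": _fmt(report.gc_bias_score),
        "mean_depth": _fmt(cov.mean_depth),
        "mapped_fraction": _fmt(cov.mapped_fraction),
        "duplicate_fraction": _fmt(cov.duplicate_fraction),
        "paired_fraction": _fmt(cov.paired_fraction),
        "total_aligned_bases": str(cov.total_aligned_bases),
        "records_seen": str(cov.records_seen),
        "analysis_span": str(cov.analysis_span),
    }


def read_text_report(path: str | os.PathLike) -> dict:
    """Parse a text report back into sections (round-trip check helper)."""
    sections: dict[str, list[list[str]]] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#") or not line:
                continue
            m = re.fullmatch(r"\[(.+)\]", line)
            if m:
                current = m.group(1)
                sections[current] = []
            elif current is not None:
                sections[current].append(line.split("\t"))
    out: dict = {"provenance": dict(sections.get("provenance", []))}
    out["summary"] = dict(sections.get("summary", []))
    for name in ("quality_concordance", "cycles", "gc_bias", "insert_summary", "insert_histogram"):
        rows = sections.get(name, [])
        if rows:
            out[name] = pd.DataFrame(rows[1:], columns=rows[0])
        else:
            out[name] = pd.DataFrame()
    return out


# ---------------------------------------------------------------------------
# XML

def write_xml(report: MetricsReport, path: str | os.PathLike) -> None:
    """Write one sample's report as XML conforming to the shipped schema."""
    root = ET.Element("alnqc_report", version=__version__)
    sample = ET.SubElement(root, "sample", label=report.label)
    prov = ET.SubElement(sample, "provenance")
    for k in sorted(report.provenance):
        ET.SubElement(prov, "entry", key=k, value=str(report.provenance[k]))
    ET.SubElement(sample, "summary", **{k: v for k, v in _summary_scalars(report).items()})
    qc = ET.SubElement(sample, "quality_concordance")
    for r in report.concordance.frame.itertuples(index=False):
        ET.SubElement(
            qc,
            "bin",
            reported_q=str(r.reported_q),
            n_matches=str(r.n_matches),
            n_mismatches=str(r.n_mismatches),
            n_bases=str(r.n_bases),
            empirical_q=_fmt(r.empirical_q),
            censored=str(int(r.censored)),
        )
    cy = ET.SubElement(sample, "cycles")
    for r in report.cycles.frame.itertuples(index=False):
        ET.SubElement(
            cy,
            "cycle",
            index=str(r.cycle),
            n_bases=str(r.n_bases),
            n_matches=str(r.n_matches),
            n_mismatches=str(r.n_mismatches),
            empirical_q=_fmt(r.empirical_q),
            censored=str(int(r.censored)),
            mean_reported_q=_fmt(r.mean_reported_q),
            frac_A=_fmt(r.frac_A),
            frac_C=_fmt(r.frac_C),
            frac_G=_fmt(r.frac_G),
            frac_T=_fmt(r.frac_T),
            frac_N=_fmt(r.frac_N),
        )
    gc = ET.SubElement(sample, "gc_bias")
    if report.gc is not None:
        gc.set("expected_depth", _fmt(report.gc.expected_depth))
        for r in report.gc.to_frame().itertuples(index=False):
            ET.SubElement(
                gc,
                "bin",
                gc_bin=str(r.gc_bin),
                n_windows=str(r.n_windows),
                weight=_fmt(r.weight),
                mean_depth=_fmt(r.mean_depth),
                normalized_depth=_fmt(r.normalized_depth),
            )
    ins = ET.SubElement(sample, "insert_sizes")
    for rg, s in sorted(report.inserts.items()):
        grp = ET.SubElement(
            ins,
            "group",
            id=rg,
            n_pairs=str(s.n_pairs),
            mode=str(s.mode),
            mean=_fmt(s.mean),
            median=_fmt(s.median),
            sd=_fmt(s.sd),
            overflow_fraction=_fmt(s.overflow_fraction),
        )
        for size in np.nonzero(s.histogram)[0]:
            ET.SubElement(
                grp,
                "point",
                size="overflow" if size == s.cap + 1 else str(int(size)),
                count=str(int(s.histogram[size])),
            )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)
    with open(path, "a") as fh:
        fh.write("\n")


def schema_path() -> str:
    return str(resources.files("alnqc").joinpath("data/report.xsd"))


def validate_xml(path: str | os.PathLike) -> None:
    """Validate a report file against the shipped XSD; raises on failure."""
    from lxml import etree

    schema = etree.XMLSchema(etree.parse(schema_path()))
    doc = etree.parse(os.fspath(path))
    schema.assertValid(doc)


def read_xml_report(path: str | os.PathLike) -> dict:
    """Parse an XML report into the same structure as read_text_report."""
    root = ET.parse(os.fspath(path)).getroot()
    sample = root.find("sample")
    out: dict = {
        "provenance": {
            e.get("key"): e.get("value") for e in sample.find("provenance")
        },
        "summary": dict(sample.find("summary").attrib),
    }

    def frame(parent_tag, cols_map):
        parent = sample.find(parent_tag)
        rows = [[e.get(src) for src, _dst in cols_map] for e in parent]
        return pd.DataFrame(rows, columns=[dst for _src, dst in cols_map])

    out["quality_concordance"] = frame(
        "quality_concordance",
        [(c, c) for c in ("reported_q", "n_matches", "n_mismatches", "n_bases", "empirical_q", "censored")],
    )
    out["cycles"] = frame(
        "cycles",
        [("index", "cycle")]
        + [(c, c) for c in (
            "n_bases", "n_matches", "n_mismatches", "empirical_q", "censored",
            "mean_reported_q", "frac_A", "frac_C", "frac_G", "frac_T", "frac_N")],
    )
    out["gc_bias"] = frame(
        "gc_bias",
        [(c, c) for c in ("gc_bin", "n_windows", "weight", "mean_depth", "normalized_depth")],
    )
    rows = []
    hist_rows = []
    for grp in sample.find("insert_sizes"):
        rows.append([grp.get(a) for a in ("id", "n_pairs", "mode", "mean", "median", "sd", "overflow_fraction")])
        for pt in grp:
            hist_rows.append([grp.get("id"), pt.get("size"), pt.get("count")])
    out["insert_summary"] = pd.DataFrame(
        rows, columns=["read_group", "n_pairs", "mode", "mean", "median", "sd", "overflow_fraction"]
    )
    out["insert_histogram"] = pd.DataFrame(
        hist_rows, columns=["read_group", "insert_size", "count"]
    )
    return out


# ---------------------------------------------------------------------------
# plots

def render_plots(
    reports: list[MetricsReport], out_dir: str | os.PathLike, fmt: str = "png"
) -> dict[str, str]:
    """Render the four diagnostic panels with all reports overlaid as
    separate series; plotted arrays are exported next to each image as TSV.
    Returns {panel name: image path}."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    def finish(fig, ax, name, title, xlab, ylab, rows, cols):
        ax.set_title(title)
        ax.set_xlabel(xlab)
        ax.set_ylabel(ylab)
        if ax.has_data():
            ax.legend(fontsize=7)
        else:
            ax.text(0.5, 0.5, "no data", ha="center", va="center", transform=ax.transAxes)
        img = os.path.join(out_dir, f"{name}.{fmt}")
        fig.savefig(img, dpi=110)
        plt.close(fig)
        pd.DataFrame(rows, columns=cols).to_csv(
            os.path.join(out_dir, f"{name}.tsv"), sep="\t", index=False
        )
        paths[name] = img

    # empirical vs reported quality, with the y = x diagonal
    fig, ax = plt.subplots(figsize=(5, 4))
    rows = []
    hi = 1.0
    for rep in reports:
        df = rep.concordance.frame
        df = df[~df["censored"]]
        if df.empty:
            continue
        ax.plot(df["reported_q"], df["empirical_q"], "o-", ms=3, label=rep.label)
        hi = max(hi, df["reported_q"].max(), df["empirical_q"].max())
        rows += [(rep.label, int(q), float(e)) for q, e in zip(df["reported_q"], df["empirical_q"])]
    ax.plot([0, hi], [0, hi], "k--", lw=0.8, label="y = x")
    finish(fig, ax, "quality_concordance", "Empirical vs reported base quality",
           "reported quality (Phred)", "empirical quality (Phred)", rows,
           ["sample", "reported_q", "empirical_q"])

    # empirical quality by machine cycle
    fig, ax = plt.subplots(figsize=(5, 4))
    rows = []
    for rep in reports:
        df = rep.cycles.frame
        if df.empty:
            continue
        keep = df[~df["censored"] & df["empirical_q"].notna()]
        ax.plot(keep["cycle"], keep["empirical_q"], "-", lw=1, label=rep.label)
        rows += [(rep.label, int(c), float(e)) for c, e in zip(keep["cycle"], keep["empirical_q"])]
    finish(fig, ax, "cycle_quality", "Empirical base quality by cycle",
           "machine cycle", "empirical quality (Phred)", rows,
           ["sample", "cycle", "empirical_q"])

    # normalised depth by GC bin, with the y = 1 uniform line
    fig, ax = plt.subplots(figsize=(5, 4))
    rows = []
    for rep in reports:
        if rep.gc is None:
            continue
        df = rep.gc.to_frame()
        ax.plot(df["gc_bin"], df["normalized_depth"], "-", lw=1, label=rep.label)
        rows += [(rep.label, int(b), float(d)) for b, d in zip(df["gc_bin"], df["normalized_depth"])]
    ax.axhline(1.0, color="k", ls="--", lw=0.8, label="uniform")
    finish(fig, ax, "gc_bias", "Depth bias by GC content",
           "GC bin (%)", "normalized depth", rows,
           ["sample", "gc_bin", "normalized_depth"])

    # insert-size distributions, one series per sample x read group
    fig, ax = plt.subplots(figsize=(5, 4))
    rows = []
    for rep in reports:
        for rg, s in sorted(rep.inserts.items()):
            sizes = np.nonzero(s.histogram[: s.cap + 1])[0]
            if not len(sizes):
                continue
            frac = s.histogram[sizes] / s.histogram.sum()
            ax.plot(sizes, frac, "-", lw=1, label=f"{rep.label}/{rg}")
            rows += [
                (rep.label, rg, int(z), int(s.histogram[z]))
                for z in sizes
            ]
    finish(fig, ax, "insert_size", "Insert size distribution",
           "insert size (bp)", "fraction of pairs", rows,
           ["sample", "read_group", "insert_size", "count"])
    return paths


# ---------------------------------------------------------------------------
# HTML

_SORT_JS = """
function sortTable(col) {
  var tb = document.getElementById('samples').tBodies[0];
  var rows = Array.from(tb.rows);
  var dir = tb.dataset.dir === 'asc' ? -1 : 1;
  tb.dataset.dir = dir === 1 ? 'asc' : 'desc';
  rows.sort(function(a, b) {
    var x = a.cells[col].innerText, y = b.cells[col].innerText;
    var nx = parseFloat(x), ny = parseFloat(y);
    if (!isNaN(nx) && !isNaN(ny)) return dir * (nx - ny);
    return dir * x.localeCompare(y);
  });
  rows.forEach(function(r) { tb.appendChild(r); });
}
"""


def _slug(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "_", label)


def build_html(
    reports: list[MetricsReport],
    out_dir: str | os.PathLike,
    plot_paths: dict[str, str] | None = None,
) -> str:
    """Assemble a static site: an index with a sortable scalar-summary
    table and one page per sample embedding the diagnostic panels.  All
    assets are local.  Returns the index path."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    if plot_paths is None:
        plot_paths = render_plots(reports, os.path.join(out_dir, "plots"))
    rel_plots = {k: os.path.relpath(v, out_dir) for k, v in plot_paths.items()}
    rows = []
    for rep in reports:
        s = _summary_scalars(rep)
        page = f"sample_{_slug(rep.label)}.html"
        rows.append(
            "<tr><td><a href=\"{page}\">{label}</a></td><td>{mse}</td>"
            "<td>{gc}</td><td>{depth}</td><td>{recs}</td></tr>".format(
                page=page,
                label=html.escape(rep.label),
                mse=s["quality_mse"],
                gc=s["gc_bias_score"],
                depth=s["mean_depth"],
                recs=s["records_seen"],
            )
        )
        _write_sample_page(rep, os.path.join(out_dir, page), rel_plots)
    index = os.path.join(out_dir, "index.html")
    with open(index, "w") as fh:
        fh.write(
            "<!DOCTYPE html><html><head><meta charset='utf-8'>"
            f"<title>alnqc report</title><script>{_SORT_JS}</script>"
            "<style>table{border-collapse:collapse}td,th{border:1px solid #999;"
            "padding:4px 8px}th{cursor:pointer;background:#eee}</style></head><body>"
            f"<h1>alnqc multi-sample report</h1><p>alnqc v{__version__}; "
            f"{len(reports)} sample(s). Click a header to sort.</p>"
            "<table id='samples'><thead><tr>"
            + "".join(
                f"<th onclick='sortTable({i})'>{h}</th>"
                for i, h in enumerate(
                    ["sample", "quality MSE", "GC bias score", "mean depth", "records"]
                )
            )
            + "</tr></thead><tbody>"
            + "".join(rows)
            + "</tbody></table></body></html>\n"
        )
    return index


def _write_sample_page(rep: MetricsReport, path: str, rel_plots: dict[str, str]) -> None:
    s = _summary_scalars(rep)
    items = "".join(
        f"<tr><td>{html.escape(k)}</td><td>{html.escape(str(v))}</td></tr>"
        for k, v in s.items()
    )
    prov = "".join(
        f"<tr><td>{html.escape(k)}</td><td>{html.escape(str(v))}</td></tr>"
        for k, v in sorted(rep.provenance.items())
    )
    imgs = "".join(
        f"<h3>{name.replace('_', ' ')}</h3><img src='{rel}' alt='{name}'>"
        for name, rel in rel_plots.items()
    )
    with open(path, "w") as fh:
        fh.write(
            "<!DOCTYPE html><html><head><meta charset='utf-8'>"
            f"<title>{html.escape(rep.label)}</title>"
            "<style>table{border-collapse:collapse}td{border:1px solid #999;"
            "padding:3px 8px}img{max-width:640px}</style></head><body>"
            f"<p><a href='index.html'>&larr; all samples</a></p>"
            f"<h1>{html.escape(rep.label)}</h1>"
            f"<h2>Summary</h2><table>{items}</table>"
            f"<h2>Panels</h2>{imgs}"
            f"<h2>Provenance</h2><table>{prov}</table>"
            "</body></html>\n"
        )
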