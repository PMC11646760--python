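"""Heatmap rendering and end-to-end pipeline orchestration.

The heatmap views mirror the published figures: a drug x stratum view of the
aggregate cardiotoxicity row (drugs on one axis in class blocks, the five
demographic strata on the other) and an outcome x drug view with the
aggregate row on top.  Colors encode only the ordinal category; the exact
palette is fixed here so images are reproducible, and every image carries a
sidecar TSV with identical cell content so nothing is image-only.

:func:`run_pipeline` chains simulate/ingest -> dedup -> eligibility ->
contingency sweep -> statistics -> classification -> detection ->
discordances, writing provenance JSON, statistics TSV, the signal table,
heatmaps, and a run log.  All outputs embed a metadata block (version,
config hash, and the statistical conventions chosen) so the under-specified
choices stay auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.patches as mpatches
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .contingency import AGGREGATE_GROUP, DEFAULT_STRATA, build_all
from .errors import PipelineError, ValidationError
from .ingest import (
    ReportSet,
    filter_eligible,
    flag_duplicates,
    read_icsr_table,
    summarize_cohort,
)
from .signals import (
    Category,
    SignalTable,
    Thresholds,
    build_signal_table,
    signal_summary,
)
from .stats import attach_statistics
from .synthetic import generate_reports, make_benchmark, paper_like_config
from .vocab import DrugPanel, OutcomeDictionary, load_drug_panel, load_outcome_groups

log = logging.getLogger(__name__)

#: Fixed, injective category -> color mapping (hex).  Only the semantics are
#: inherited from the published legend; the exact shades are package policy.
CATEGORY_COLORS: Mapping[Category, str] = {
    Category.NO_REPORTS: "#f2f2f2",
    Category.FEW_CASES: "#ffffff",
    Category.INSUFFICIENT: "#c8e6c9",
    Category.NULL_SIGNAL: "#2e7d32",
    Category.ELEVATED_NS: "#f4a6a0",
    Category.SIGNAL: "#d32f2f",
    Category.STRONG_SIGNAL: "#7f0000",
}

#: Glyph drawn inside a cell (only the no-reports dash).
CATEGORY_GLYPHS: Mapping[Category, str] = {Category.NO_REPORTS: "-"}


@dataclass
class HeatmapLayout:
    """Row/column orders for one heatmap view.

    ``kind="drug-stratum"`` plots drugs (rows, grouped by class) against
    strata for a single outcome group (default the aggregate row);
    ``kind="group-drug"`` plots outcome groups (rows, aggregate first)
    against drugs for a single stratum.
    """

    kind: str
    row_order: tuple[str, ...]
    col_order: tuple[str, ...]
    fixed_group: str = AGGREGATE_GROUP
    fixed_stratum: str = "all"
    row_blocks: tuple[str, ...] = ()      # per-row class labels, optional
    palette: Mapping[Category, str] = field(default_factory=lambda: dict(CATEGORY_COLORS))
    title: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("drug-stratum", "group-drug"):
            raise ValidationError(f"unknown layout kind {self.kind!r}")
        if len(set(self.palette.values())) != len(self.palette):
            raise ValidationError("palette must map categories to distinct colors")

    def cell_key(self, row: str, col: str) -> tuple[str, str, str]:
        if self.kind == "drug-stratum":
            return (row, self.fixed_group, col)
        return (col, row, self.fixed_stratum)


def drug_stratum_layout(
    panel: DrugPanel,
    strata: Sequence[str] = tuple(s.label for s in DEFAULT_STRATA),
    group: str = AGGREGATE_GROUP,
) -> HeatmapLayout:
    """Drugs (class blocks) x strata for one outcome group."""
    return HeatmapLayout(
        kind="drug-stratum",
        row_order=panel.names,
        col_order=tuple(strata),
        fixed_group=group,
        row_blocks=tuple(e.drug_class for e in panel.entries),
        title=f"{group} by stratum",
    )


def group_drug_layout(
    panel: DrugPanel,
    dictionary: OutcomeDictionary,
    stratum: str = "all",
    include_aggregate: bool = True,
) -> HeatmapLayout:
    """Outcome groups (aggregate row on top) x drugs for one stratum."""
    rows = ((AGGREGATE_GROUP,) if include_aggregate else ()) + dictionary.names
    return HeatmapLayout(
        kind="group-drug",
        row_order=rows,
        col_order=panel.names,
        fixed_stratum=stratum,
        title=f"outcome groups by drug ({stratum})",
    )


def render_heatmap(
    st: SignalTable,
    layout: HeatmapLayout,
    out_path: str | Path,
) -> tuple[Path, Path]:
    """Write the heatmap image plus a sidecar TSV with identical content.

    Returns ``(image_path, tsv_path)``.  Every layout cell must exist in the
    signal table; missing cells raise with the full missing list.
    """
    out_path = Path(out_path)
    missing = []
    cells = {}
    for row in layout.row_order:
        for col in layout.col_order:
            key = layout.cell_key(row, col)
            cell = st.cell(*key)
            if cell is None:
                missing.append(key)
            else:
                cells[(row, col)] = cell
    if missing:
        raise ValidationError(
            f"signal table is missing {len(missing)} cell(s) for this layout: "
            + "; ".join(map(str, missing[:10]))
        )

    n_rows, n_cols = len(layout.row_order), len(layout.col_order)
    codes = np.zeros((n_rows, n_cols), dtype=int)
    for i, row in enumerate(layout.row_order):
        for j, col in enumerate(layout.col_order):
            codes[i, j] = int(cells[(row, col)].category)

    from matplotlib.colors import BoundaryNorm, ListedColormap

    cats = sorted(layout.palette, key=int)
    cmap = ListedColormap([layout.palette[c] for c in cats])
    norm = BoundaryNorm([int(c) - 0.5 for c in cats] + [int(cats[-1]) + 0.5], cmap.N)

    fig_h = max(2.5, 0.28 * n_rows + 1.5)
    fig_w = max(4.0, 0.42 * n_cols + 3.0)
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    ax.imshow(codes, cmap=cmap, norm=norm, aspect="auto")
    ax.set_xticks(range(n_cols))
    ax.set_xticklabels(layout.col_order, rotation=90, fontsize=7)
    row_labels = [
        f"{blk} | {name}" if blk else name
        for name, blk in zip(
            layout.row_order,
            layout.row_blocks or ("",) * n_rows,
        )
    ]
    ax.set_yticks(range(n_rows))
    ax.set_yticklabels(row_labels, fontsize=7)
    for i in range(n_rows):
        for j in range(n_cols):
            glyph = CATEGORY_GLYPHS.get(Category(codes[i, j]))
            if glyph:
                ax.text(j, i, glyph, ha="center", va="center", fontsize=8)
    handles = [
        mpatches.Patch(facecolor=layout.palette[c], edgecolor="0.6", label=c.name)
        for c in cats
    ]
    ax.legend(handles=handles, bbox_to_anchor=(1.02, 1), loc="upper left", fontsize=6)
    if layout.title:
        ax.set_title(layout.title, fontsize=9)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)

    tsv_path = out_path.with_suffix(".tsv")
    rows = []
    for row in layout.row_order:
        for col in layout.col_order:
            cell = cells[(row, col)]
            rows.append(
                {
                    "row": row, "col": col,
                    "drug": cell.drug, "group": cell.group, "stratum": cell.stratum,
                    "category": cell.category.name,
                    "a": cell.a, "ror": cell.ror,
                    "p_fisher": cell.p_fisher, "ic025": cell.ic025,
                }
            )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    return out_path, tsv_path


@dataclass
class PipelineConfig:
    """End-to-end run configuration: either an input path or a simulation
    profile, plus vocabulary paths and statistical conventions."""

    outdir: str | Path = "vigisig_out"
    input_path: str | Path | None = None
    profile: str | None = None            # paper-like | null | stress
    n_reports: int | None = None
    seed: int = 0
    panel_path: str | Path | None = None
    dictionary_path: str | Path | None = None
    roles: tuple[str, ...] | None = None
    keep_duplicates: bool = False
    thresholds: Thresholds = field(default_factory=Thresholds)
    ror_form: str = "odds"
    haldane: bool = False
    ic_method: str = "approx"
    signal_criterion: str = "aggregate"
    make_plots: bool = True

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            return str(o)

        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory results plus the paths of everything written."""

    report_set: ReportSet
    statistics: pd.DataFrame
    signal_table: SignalTable
    summary: Mapping
    artifacts: dict[str, Path]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ValidationError:
                raise
            except Exception as e:          # pragma: no cover - defensive
                raise PipelineError(f"stage {name!r} failed: {e}") from e
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write all artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("vigisig")
    root.addHandler(handler)
    try:
        return _run(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> PipelineResult:
    panel = load_drug_panel(config.panel_path)
    dictionary = load_outcome_groups(config.dictionary_path)

    if (config.input_path is None) == (config.profile is None):
        raise ValidationError("exactly one of input_path or profile must be given")

    if config.profile is not None:
        rs, _truth = _stage("simulate")(make_benchmark)(
            config.profile, config.n_reports, config.seed, panel, dictionary
        )
    else:
        rs = _stage("ingest")(read_icsr_table)(config.input_path)
    log.info("read %d reports", rs.provenance.total_read)

    if not config.keep_duplicates:
        rs = _stage("deduplicate")(flag_duplicates)(rs)
    rs = _stage("eligibility")(filter_eligible)(rs)
    cohort = summarize_cohort(rs)

    tables = _stage("contingency")(build_all)(
        rs, panel, dictionary, DEFAULT_STRATA,
        roles=config.roles, include_aggregate=True,
    )
    stats_df = _stage("statistics")(attach_statistics)(
        tables, panel,
        form=config.ror_form, haldane=config.haldane, ic_method=config.ic_method,
    )
    st = _stage("signals")(build_signal_table)(stats_df, config.thresholds)
    summary = signal_summary(st, panel, criterion=config.signal_criterion)

    metadata = {
        "tool": "vigisig",
        "version": __version__,
        "config_hash": config.config_hash(),
        "conventions": {
            "ror_form": config.ror_form,
            "haldane": config.haldane,
            "ci_method": "woolf log-normal, z=1.96",
            "fisher": "two-sided probability-mass, rel. tie tolerance 1e-7",
            "ic_method": config.ic_method,
            "aggregate_row": AGGREGATE_GROUP,
            "signal_criterion": config.signal_criterion,
            "thresholds": dataclasses.asdict(config.thresholds),
            "roles_counted_as_exposure": list(config.roles) if config.roles else "all",
        },
    }

    artifacts: dict[str, Path] = {}
    prov_path = outdir / "provenance.json"
    prov_path.write_text(json.dumps(
        {"provenance": rs.provenance.to_dict(), "cohort": cohort.to_dict(),
         "metadata": metadata},
        indent=2,
    ))
    artifacts["provenance"] = prov_path

    stats_path = outdir / "statistics.tsv"
    stats_df.to_csv(stats_path, sep="\t", index=False, float_format="%.10g")
    artifacts["statistics"] = stats_path

    sig_path = outdir / "signals.tsv"
    pd.DataFrame(
        [
            {
                "drug": c.drug, "class": panel.class_of(c.drug), "group": c.group,
                "stratum": c.stratum, "category": c.category.name,
                "a": c.a, "ror": c.ror, "p_fisher": c.p_fisher, "ic025": c.ic025,
            }
            for c in st.cells
        ]
    ).to_csv(sig_path, sep="\t", index=False, float_format="%.10g")
    artifacts["signals"] = sig_path

    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps({"summary": summary, "metadata": metadata}, indent=2))
    artifacts["summary"] = summary_path

    if config.make_plots:
        img, side = render_heatmap(
            st, drug_stratum_layout(panel), outdir / "heatmap_overall.png"
        )
        artifacts["heatmap_overall"] = img
        artifacts["heatmap_overall_tsv"] = side
        img, side = render_heatmap(
            st, group_drug_layout(panel, dictionary), outdir / "heatmap_groups.png"
        )
        artifacts["heatmap_groups"] = img
        artifacts["heatmap_groups_tsv"] = side

    return PipelineResult(
        report_set=rs,
        statistics=stats_df,
        signal_table=st,
        summary={"summary": summary, "metadata": metadata,
                 "provenance": rs.provenance.to_dict(), "cohort": cohort.to_dict()},
        artifacts=artifacts,
    )
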