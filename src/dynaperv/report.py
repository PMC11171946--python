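"""Cohort summary tables and markdown rendering.

Reproduces the layout of the study's demographic table (severity banding,
occlusion sites, treatment outcome) and the per-category imaging table, from
any cohort DataFrame in the package schema.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import truth_table

__all__ = ["SEVERITY_BANDS", "severity_band", "table_demographics", "table_by_category",
           "render_summary", "render_markdown_table"]

#: NIHSS severity bands: non-overlapping, jointly covering 0..42.
SEVERITY_BANDS = (
    ("minor", 0, 4),
    ("moderate", 5, 15),
    ("moderate-severe", 16, 20),
    ("severe", 21, 42),
)


def severity_band(nihss) -> pd.Categorical:
    """Band NIHSS scores into minor / moderate / moderate-severe / severe."""
    x = np.asarray(nihss, dtype=float)
    if np.any((x < 0) | (x > 42) | ~np.isfinite(x)):
        raise ValueError("NIHSS scores must lie in 0..42")
    labels = [b[0] for b in SEVERITY_BANDS]
    edges = [-0.5] + [b[2] + 0.5 for b in SEVERITY_BANDS]
    return pd.cut(x, bins=edges, labels=labels)


def table_demographics(cohort: pd.DataFrame) -> pd.DataFrame:
    """Demographics / severity / site / treatment summary (one row per item)."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    n = len(cohort)
    rows = [("N", n, ""), ("median age (range)",
             float(cohort["age"].median()),
             f"{cohort['age'].min():.0f}-{cohort['age'].max():.0f}")]
    n_f = int((cohort["sex"] == "F").sum())
    rows.append(("female N (%)", n_f, f"{100 * n_f / n:.1f}"))
    bands = severity_band(cohort["nihss_admit"]).value_counts().reindex(
        [b[0] for b in SEVERITY_BANDS]
    )
    for name, count in bands.items():
        rows.append((f"severity {name}", int(count), f"{100 * count / n:.1f}"))
    for site, count in cohort["occlusion_site"].value_counts().items():
        rows.append((f"occlusion {site}", int(count), f"{100 * count / n:.1f}"))
    rows.append(("clot length mean (SD) mm", float(cohort["clot_length_mm"].mean()),
                 f"{cohort['clot_length_mm'].std(ddof=1):.1f}"))
    n_success = int(cohort["success"].sum())
    rows.append(("TICI 2c-3 N (%)", n_success, f"{100 * n_success / n:.1f}"))
    rows.append(("TICI 0-2b N (%)", n - n_success, f"{100 * (n - n_success) / n:.1f}"))
    return pd.DataFrame(rows, columns=["characteristic", "value", "detail"])


def table_by_category(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-category imaging/outcome summary; empty categories render N = 0."""
    return truth_table(cohort)


def render_markdown_table(df: pd.DataFrame, float_fmt: str = "{:.2f}") -> str:
    """Minimal GitHub-style markdown table (no external dependencies)."""
    df = df.reset_index() if df.index.name else df
    def fmt(v):
        if isinstance(v, float):
            return "" if np.isnan(v) else float_fmt.format(v)
        return str(v)
    header = "| " + " | ".join(df.columns.astype(str)) + " |"
    sep = "| " + " | ".join("---" for _ in df.columns) + " |"
    body = ["| " + " | ".join(fmt(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *body])


def render_summary(cohort: pd.DataFrame, results: pd.DataFrame | None = None,
                   header: dict | None = None) -> str:
    """Render the full markdown report: header, demographics, per-category
    table, and (optionally) the tidy regression results."""
    parts = ["# Dynamic-perviousness analysis report", ""]
    if header:
        parts += [f"- **{k}**: {v}" for k, v in header.items()] + [""]
    parts += ["## Cohort demographics", "", render_markdown_table(table_demographics(cohort)), ""]
    parts += ["## Per-category summary", "",
              render_markdown_table(table_by_category(cohort).reset_index()), ""]
    if results is not None and len(results):
        parts += ["## Regression results", "", render_markdown_table(results, "{:.3f}"), ""]
    return "\n".join(parts)
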