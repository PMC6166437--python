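"""Publication-shaped table rendering.

Ratios display to a configured number of decimals with an en-dash CI
separator — ``1.46 (1.36–1.56)`` — reference levels carry ``(ref)``,
and significance versus a reference category is marked with a
superscript-style letter. Underlying CSV output keeps full precision;
rounding happens only here.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .errors import RenderingError

TABLE_STYLES = ("round_by_outcome", "stratified_panel")


def format_ratio_ci(
    ratio: float,
    ci: Optional[tuple[float, float]] = None,
    decimals: int = 2,
    letters: str = "",
) -> str:
    """``1.46 (1.36–1.56)a`` — the display form of one estimate."""
    s = f"{ratio:.{decimals}f}"
    if ci is not None:
        s += f" ({ci[0]:.{decimals}f}–{ci[1]:.{decimals}f})"
    return s + letters


def render_table(
    rows: Sequence[dict],
    style: str,
    decimals: int = 2,
) -> str:
    """Render result rows as a markdown table.

    ``round_by_outcome`` rows: ``{"round": ..., "category": ...,
    "ratio": ..., "ci": (lo, hi) | None, "expanded_ratio": float | None,
    "letters": str}`` — one output line per round, one column group per
    category; every input row of one line must carry the same round.

    ``stratified_panel`` rows: ``{"axis": ..., "level": ...,
    "is_reference": bool, "category": ..., "ratio": ..., "ci": ...,
    "letters": str}`` — one line per (axis, level).
    """
    if style not in TABLE_STYLES:
        raise RenderingError(f"unknown table style: {style!r}")
    if style == "round_by_outcome":
        return _render_round_by_outcome(rows, decimals)
    return _render_stratified(rows, decimals)


def _categories_in(rows: Sequence[dict]) -> list[str]:
    cats: list[str] = []
    for r in rows:
        if r["category"] not in cats:
            cats.append(r["category"])
    return cats


def _render_round_by_outcome(rows: Sequence[dict], decimals: int) -> str:
    cats = _categories_in(rows) or ["abortion", "loss", "birth"]
    has_expanded = any(r.get("expanded_ratio") is not None for r in rows)
    header = ["Survey period"]
    for c in cats:
        header.append(f"{c} ratio (95% CI)")
        if has_expanded:
            header.append(f"{c} expanded")
    lines = ["| " + " | ".join(header) + " |",
             "|" + "---|" * len(header)]
    by_round: dict[str, list[dict]] = {}
    for r in rows:
        by_round.setdefault(r["round"], []).append(r)
    for rnd, rrows in by_round.items():
        if len({x["round"] for x in rrows}) != 1:
            raise RenderingError("mixed rounds in a single table line")
        cells = [rnd]
        by_cat = {x["category"]: x for x in rrows}
        for c in cats:
            x = by_cat.get(c)
            if x is None:
                cells.append("")
                if has_expanded:
                    cells.append("")
                continue
            cells.append(
                format_ratio_ci(x["ratio"], x.get("ci"), decimals, x.get("letters", ""))
            )
            if has_expanded:
                exp = x.get("expanded_ratio")
                cells.append("" if exp is None else f"{exp:.{decimals}f}")
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def _render_stratified(rows: Sequence[dict], decimals: int) -> str:
    cats = _categories_in(rows)
    header = ["Characteristic"] + [f"{c} ratio (95% CI)" for c in cats]
    lines = ["| " + " | ".join(header) + " |",
             "|" + "---|" * len(header)]
    seen: list[tuple[str, str, bool]] = []
    for r in rows:
        key = (r["axis"], r["level"], bool(r.get("is_reference")))
        if key not in seen:
            seen.append(key)
    for axis, level, is_ref in seen:
        name = f"{level} (ref)" if is_ref else level
        cells = [name]
        for c in cats:
            match = [
                r for r in rows
                if r["axis"] == axis and r["level"] == level and r["category"] == c
            ]
            if not match:
                cells.append("")
                continue
            x = match[0]
            cells.append(
                format_ratio_ci(x["ratio"], x.get("ci"), decimals, x.get("letters", ""))
            )
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
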