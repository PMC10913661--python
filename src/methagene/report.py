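"""Self-contained static HTML report assembly.

Figures are embedded base64, tables rendered inline; the file opens
without network access and regenerating it from identical artifacts yields
identical bytes (no timestamps, no random identifiers).
"""

from __future__ import annotations

import base64
import html
from pathlib import Path

import pandas as pd

__all__ = ["render_report"]

_PAGE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em auto; max-width: 70em; color: #222; }}
h1 {{ border-bottom: 2px solid #444; padding-bottom: 0.2em; }}
h2 {{ margin-top: 2em; color: #2a4d69; }}
table {{ border-collapse: collapse; font-size: 0.85em; margin: 1em 0; }}
th, td {{ border: 1px solid #bbb; padding: 0.25em 0.6em; text-align: right; }}
th {{ background: #eef; }}
img {{ max-width: 100%; margin: 0.5em 0; }}
.meta {{ color: #777; font-size: 0.8em; }}
</style>
</head>
<body>
<h1>{title}</h1>
<p class="meta">{subtitle}</p>
{sections}
</body>
</html>
"""

_MIME = {".png": "image/png", ".svg": "image/svg+xml", ".jpg": "image/jpeg"}


def _embed_image(path) -> str:
    path = Path(path)
    mime = _MIME.get(path.suffix.lower())
    if mime is None:
        raise ValueError(f"cannot embed {path}: unsupported image type")
    data = base64.b64encode(path.read_bytes()).decode("ascii")
    return f'<img src="data:{mime};base64,{data}" alt="{html.escape(path.stem)}">'


def _render_item(item) -> str:
    """An item is a figure path, a DataFrame, or a plain-text string."""
    if isinstance(item, pd.DataFrame):
        return item.to_html(index=False, float_format=lambda v: f"{v:.4g}", border=0)
    item_path = Path(str(item))
    if item_path.suffix.lower() in _MIME:
        return _embed_image(item_path)
    return f"<p>{html.escape(str(item))}</p>"


def render_report(
    sections: dict,
    path,
    title: str = "Methylation analysis report",
    subtitle: str = "",
) -> None:
    """Assemble a single self-contained HTML file.

    Parameters
    ----------
    sections
        Ordered mapping of section heading -> list of items; each item is a
        figure file path (embedded base64), a DataFrame (inline table) or a
        string (paragraph). An empty mapping is an error — a report must
        report something.
    path
        Output .html path.
    """
    if not sections or all(not items for items in sections.values()):
        raise ValueError("no artifacts to report")
    parts = []
    for heading, items in sections.items():
        parts.append(f"<h2>{html.escape(heading)}</h2>")
        for item in items:
            parts.append(_render_item(item))
    doc = _PAGE.format(
        title=html.escape(title),
        subtitle=html.escape(subtitle),
        sections="\n".join(parts),
    )
    Path(path).write_bytes(doc.encode("utf-8"))
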