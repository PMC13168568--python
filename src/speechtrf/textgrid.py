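"""Minimal Praat TextGrid (long text format) reading and writing.

Only interval tiers are supported; point tiers are skipped. This covers the
phoneme/word segmentations produced by forced aligners (WebMAUS) and manual
Praat annotation, which are the segmentation inputs of this package.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["Interval", "IntervalTier", "read_textgrid", "write_textgrid"]


@dataclass
class Interval:
    xmin: float
    xmax: float
    text: str


@dataclass
class IntervalTier:
    name: str
    xmin: float
    xmax: float
    intervals: list[Interval] = field(default_factory=list)


_KV = re.compile(r'^\s*(\w+)\s*=\s*(.*?)\s*$')


def _parse_value(raw: str):
    raw = raw.strip()
    if raw.startswith('"'):
        # Praat escapes a quote inside a string by doubling it.
        return raw[1:-1].replace('""', '"')
    return float(raw)


def read_textgrid(path) -> dict[str, IntervalTier]:
    """Parse a long-format TextGrid into a mapping of tier name -> tier."""
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    tiers: dict[str, IntervalTier] = {}
    tier: IntervalTier | None = None
    in_interval_tier = False
    pending: dict[str, float | str] = {}

    def flush_interval():
        nonlocal pending
        if tier is not None and {"xmin", "xmax", "text"} <= pending.keys():
            tier.intervals.append(
                Interval(float(pending["xmin"]), float(pending["xmax"]),
                         str(pending["text"])))
        pending = {}

    for line in lines:
        stripped = line.strip()
        if stripped.startswith("item ["):
            flush_interval()
            tier = None
            in_interval_tier = False
            continue
        if stripped.startswith("intervals ["):
            flush_interval()
            continue
        m = _KV.match(line)
        if not m:
            continue
        key, raw = m.group(1), m.group(2)
        if key == "class":
            in_interval_tier = _parse_value(raw) == "IntervalTier"
        elif key == "name" and in_interval_tier:
            tier = IntervalTier(str(_parse_value(raw)), 0.0, 0.0)
            tiers[tier.name] = tier
        elif tier is not None and key in ("xmin", "xmax", "text"):
            if key == "text":
                pending["text"] = _parse_value(raw)
            elif pending or key == "xmin":
                pending[key] = float(_parse_value(raw))
            # tier-level xmin/xmax arrive before any interval; keep them too
            if key in ("xmin", "xmax") and not tier.intervals and "text" not in pending:
                setattr(tier, key, float(_parse_value(raw)))
    flush_interval()
    return tiers


def _quote(text: str) -> str:
    return '"' + text.replace('"', '""') + '"'


def write_textgrid(path, tiers: list[IntervalTier], xmin: float, xmax: float) -> None:
    """Write interval tiers as a long-format TextGrid file."""
    out = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {xmin}",
        f"xmax = {xmax}",
        "tiers? <exists>",
        f"size = {len(tiers)}",
        "item []:",
    ]
    for i, tier in enumerate(tiers, start=1):
        out += [
            f"    item [{i}]:",
            '        class = "IntervalTier"',
            f"        name = {_quote(tier.name)}",
            f"        xmin = {tier.xmin}",
            f"        xmax = {tier.xmax}",
            f"        intervals: size = {len(tier.intervals)}",
        ]
        for k, iv in enumerate(tier.intervals, start=1):
            out += [
                f"        intervals [{k}]:",
                f"            xmin = {iv.xmin}",
                f"            xmax = {iv.xmax}",
                f"            text = {_quote(iv.text)}",
            ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(out) + "\n")
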