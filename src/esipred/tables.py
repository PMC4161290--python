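"""Loaders for the parameter tables shipped with the package."""

from __future__ import annotations

from importlib import resources


def _read_tsv(name: str) -> list[list[str]]:
    text = resources.files("esipred.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def load_gb_table(path=None) -> dict[str, float]:
    """Intrinsic gas-phase basicities (kJ/mol) keyed by site kind.

    Reads the shipped default table unless ``path`` points at a
    user-supplied TSV with columns (kind, gb_kj_per_mol).
    """
    if path is None:
        rows = _read_tsv("gb_intrinsic.tsv")
    else:
        with open(path) as fh:
            rows = [line.strip().split("\t") for line in fh
                    if line.strip() and not line.startswith("#")]
    header, *body = rows
    return {kind: float(gb) for kind, gb in body}


def load_collision_radii(path=None) -> dict[str, float]:
    """Per-element collision radii (nm)."""
    if path is None:
        rows = _read_tsv("collision_radii.tsv")
    else:
        with open(path) as fh:
            rows = [line.strip().split("\t") for line in fh
                    if line.strip() and not line.startswith("#")]
    header, *body = rows
    return {el.upper(): float(r) for el, r in body}
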