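"""Catalog of the published serum-miRNA diagnostic indices I–VIII.

Each index is a linear score over log2 marker levels with the score >= 0
sarcoma decision rule; e.g. Index VI is

    0.87·miR-4736 + 0.52·miR-6836-3p − 1.14·miR-4281 + 1.31·miR-762
    + 0.59·miR-658 − 0.22·miR-4649-5p − 0.15·miR-4665-3p − 15.9.

The catalog ships as a JSON data file in the IndexModel format.
"""

from __future__ import annotations

import json
from importlib import resources

from .discriminant import IndexModel

__all__ = ["INDEX_NAMES", "published_index", "published_catalog"]

INDEX_NAMES = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")


def _load() -> dict[str, dict]:
    with resources.files("seromir.data").joinpath("published_indices.json").open(
        encoding="utf-8"
    ) as fh:
        return json.load(fh)


def published_catalog() -> dict[str, IndexModel]:
    """All eight published indices, keyed by roman numeral."""
    return {key: IndexModel.from_dict(d) for key, d in _load().items()}


def published_index(name: str) -> IndexModel:
    """Look up one published index by roman numeral (``"I"`` .. ``"VIII"``)."""
    catalog = _load()
    if name not in catalog:
        raise KeyError(
            f"unknown index {name!r}; valid names are {', '.join(INDEX_NAMES)}"
        )
    return IndexModel.from_dict(catalog[name])
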