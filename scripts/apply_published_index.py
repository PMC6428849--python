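"""Apply a published index to a locally supplied GEO series-matrix file.

Optional integration helper: loads an already-normalized expression table
deposited in the series-matrix text layout, scores every sample with the
chosen published index (default VI), and — when the sample
characteristics encode malignant vs non-malignant groups — reports
diagnostic performance at the score >= 0 rule.

Usage:  python scripts/apply_published_index.py SERIES_MATRIX.txt [--index VI]
"""

from __future__ import annotations

import argparse
import json
import sys

import numpy as np

from seromir.catalog import published_index
from seromir.discriminant import index_scores
from seromir.geo import read_series_matrix
from seromir.performance import evaluate


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("series_matrix", help="local series-matrix text file")
    parser.add_argument("--index", default="VI", help="published index numeral")
    args = parser.parse_args()

    model = published_index(args.index)
    cm = read_series_matrix(args.series_matrix)
    scores = index_scores(model, cm.matrix)
    out = {
        "index": model.name,
        "n_samples": int(len(scores)),
        "scores": {sid: round(float(s), 4) for sid, s in scores.items()},
    }
    groups = cm.groups
    labels = (groups == "malignant").astype(int)
    if 0 < labels.sum() < len(labels):
        out["performance"] = evaluate(scores.to_numpy(), labels).to_dict()
    else:
        print("note: group characteristics absent or single-class; "
              "reporting scores only", file=sys.stderr)
    json.dump(out, sys.stdout, indent=2)
    print()


if __name__ == "__main__":
    main()
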