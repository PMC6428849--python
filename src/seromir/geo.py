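"""Reader for GEO series-matrix text files.

Parses the ``!Sample_*`` header lines and the tab-separated expression
table between ``!series_matrix_table_begin`` and
``!series_matrix_table_end``.  Values are taken as already normalized; no
re-processing is applied.  Sample characteristics of the form
``key: value`` are mapped onto :class:`~seromir.preprocess.SampleMeta`
fields where present (group, age, sex, cohort); absent fields fall back to
neutral defaults so partially annotated series still load.
"""

from __future__ import annotations

import io
from pathlib import Path

import pandas as pd

from .preprocess import COHORTS, GROUPS, CohortMatrix, SampleMeta

__all__ = ["SeriesMatrixError", "read_series_matrix"]


class SeriesMatrixError(ValueError):
    """Malformed series-matrix file; the message carries the line number."""


def _parse_characteristics(lines: list[tuple[int, str]], n_samples: int) -> list[dict]:
    per_sample: list[dict] = [{} for _ in range(n_samples)]
    for lineno, line in lines:
        fields = [f.strip().strip('"') for f in line.rstrip("\n").split("\t")[1:]]
        if len(fields) != n_samples:
            raise SeriesMatrixError(
                f"line {lineno}: {len(fields)} characteristics for {n_samples} samples"
            )
        for d, field in zip(per_sample, fields):
            if ":" in field:
                key, value = field.split(":", 1)
                d[key.strip().lower()] = value.strip()
    return per_sample


def read_series_matrix(path) -> CohortMatrix:
    """Load a GEO series-matrix text file into a :class:`CohortMatrix`."""
    path = Path(path)
    char_lines: list[tuple[int, str]] = []
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("!series_matrix_table_begin"):
                in_table, saw_begin = True, True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table, saw_end = False, True
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_characteristics"):
                char_lines.append((lineno, line))
    if not saw_begin:
        raise SeriesMatrixError(f"{path}: no !series_matrix_table_begin marker found")
    if not saw_end:
        raise SeriesMatrixError(f"{path}: no !series_matrix_table_end marker found")
    if not table_lines:
        raise SeriesMatrixError(f"{path}: empty expression table")
    try:
        df = pd.read_csv(io.StringIO("".join(table_lines)), sep="\t", index_col=0)
    except Exception as exc:
        raise SeriesMatrixError(f"{path}: could not parse expression table: {exc}") from exc
    df.columns = [str(c).strip().strip('"') for c in df.columns]
    df.index = [str(i).strip().strip('"') for i in df.index]

    chars = _parse_characteristics(char_lines, df.shape[1])
    samples = []
    for sample_id, d in zip(df.columns, chars):
        group = d.get("group", "other_cancer")
        if group not in GROUPS:
            group = "other_cancer"
        cohort = d.get("cohort", "exploratory")
        if cohort not in COHORTS:
            cohort = "exploratory"
        sex = d.get("sex", "F")
        sex = "M" if sex.upper().startswith("M") else "F"
        try:
            age = float(d.get("age", "nan"))
        except ValueError:
            age = float("nan")
        if not age == age:  # NaN
            age = 0.0
        samples.append(SampleMeta(sample_id=sample_id, group=group, age=age,
                                  sex=sex, cohort=cohort))
    return CohortMatrix(matrix=df.astype(float), samples=samples)
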