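"""Flexibility vs function: gating charge, Q10 and stretch shifts.

Joins computed (or transcribed) flexibility indices with per-channel
functional annotations — total gating charge e0, temperature
coefficients Q10 of activation/inactivation kinetics, and the
stretch-induced half-activation shift ΔV1/2 — and quantifies the
relationships: a modified single-exponential trend fit
``f(x) = a·exp[b/(x + c)]``, Spearman rank correlations with
permutation p-values, and exact class-vs-trait association tests.

Interval-valued annotations (e.g. a charge reported as "12 to 16")
are kept as intervals and reduced to midpoints for fitting.
"""

from __future__ import annotations

import csv
import io
import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

Interval = tuple[float, float]

#: Fixed default seed of the Monte-Carlo permutation fallback.
DEFAULT_PERMUTATION_SEED: int = 20190


class TableParseError(ValueError):
    """A fixture row could not be parsed."""


class FitConvergenceError(RuntimeError):
    """The nonlinear fit failed to converge from every start."""


@dataclass(frozen=True)
class FunctionalRecord:
    """One channel/domain row of the functional annotation table."""

    channel: str
    domain: str | None = None
    s3_index: float | None = None
    s3s4_index: float | None = None
    s1s4_index: float | None = None
    charge_e0: Interval | None = None
    q10_act: Interval | None = None
    q10_inact: Interval | None = None
    dv12_shift: Interval | None = None
    mechanosensitive: bool | None = None
    notes: str = ""
    source_table: str = ""

    @property
    def key(self) -> str:
        return f"{self.channel} {self.domain}" if self.domain else self.channel


@dataclass(frozen=True)
class FitResult:
    a: float
    b: float
    c: float
    r_squared: float
    n_points: int
    ss_res: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.a * np.exp(self.b / (np.asarray(x, dtype=float) + self.c))


def midpoint(interval: Interval | None) -> float | None:
    if interval is None:
        return None
    return 0.5 * (interval[0] + interval[1])


def parse_value(text: str | None) -> Interval | None:
    """Parse one annotation cell into an interval (or None when absent).

    Grammar: ``n.d.`` / ``-`` / ``–`` / empty → absent; ``~ x`` → point;
    ``> x`` → point at the stated bound; ``a to b`` / ``a – b`` (spaced
    dash) → interval; ``x ± y`` → [x−y, x+y]; ``p ; q`` → envelope of
    the parts.  Plain numbers are point intervals.
    """
    if text is None:
        return None
    cell = text.strip()
    if cell in ("", "-", "–", "n.d.", "nd", "NA"):
        return None
    if ";" in cell:
        parts = [parse_value(p) for p in cell.split(";")]
        parts = [p for p in parts if p is not None]
        if not parts:
            return None
        return (min(p[0] for p in parts), max(p[1] for p in parts))
    def atom(s: str) -> float:
        s = s.strip()
        while s and s[0] in "~><":  # approximate / bound markers
            s = s[1:].strip()
        return float(s)

    try:
        if "±" in cell:
            center_s, err_s = cell.split("±")
            center, err = atom(center_s), atom(err_s)
            return (center - err, center + err)
        for sep in (" to ", " – ", " — "):
            if sep in cell:
                lo_s, hi_s = cell.split(sep)
                lo, hi = atom(lo_s), atom(hi_s)
                return (min(lo, hi), max(lo, hi))
        v = atom(cell)
        return (v, v)
    except ValueError as exc:
        raise TableParseError(f"cannot parse value {text!r}") from exc


def _parse_float(text: str | None) -> float | None:
    interval = parse_value(text)
    if interval is None:
        return None
    if interval[0] != interval[1]:
        raise TableParseError(f"expected a single number, got range {text!r}")
    return interval[0]


def _read_fixture_rows(path_or_name: str | Path) -> list[dict[str, str]]:
    path = Path(path_or_name)
    if path.exists():
        text = path.read_text()
    else:
        text = resources.files("vsdflex.data").joinpath(str(path_or_name)).read_text()
    rows = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    return list(csv.DictReader(io.StringIO("\n".join(rows)), delimiter="\t"))


def load_functional_table(
    table1: str | Path = "functional_table1.tsv",
    table2: str | Path = "functional_table2.tsv",
) -> list[FunctionalRecord]:
    """Load the packaged functional fixture (both tables).

    The two tables are concatenated; channels appearing in both keep
    one record per table (their transcribed indices differ slightly),
    distinguished by ``source_table``.
    """
    records: list[FunctionalRecord] = []
    for row in _read_fixture_rows(table1):
        try:
            records.append(
                FunctionalRecord(
                    channel=row["channel"].strip(),
                    domain=None if row["domain"].strip() in ("-", "") else row["domain"].strip(),
                    s3_index=_parse_float(row["s3_index"]),
                    s3s4_index=_parse_float(row["s3s4_index"]),
                    s1s4_index=_parse_float(row["s1s4_index"]),
                    charge_e0=parse_value(row["charge_e0"]),
                    q10_act=parse_value(row["q10_act"]),
                    q10_inact=parse_value(row["q10_inact"]),
                    notes=row.get("notes", "").strip("-").strip(),
                    source_table="table1",
                )
            )
        except (KeyError, TableParseError) as exc:
            raise TableParseError(f"table1 row {row.get('channel')!r}: {exc}") from exc
    for row in _read_fixture_rows(table2):
        try:
            records.append(
                FunctionalRecord(
                    channel=row["channel"].strip(),
                    domain=None if row["domain"].strip() in ("-", "") else row["domain"].strip(),
                    s3_index=_parse_float(row["s3_index"]),
                    s3s4_index=_parse_float(row["s3s4_index"]),
                    charge_e0=parse_value(row["charge_e0"]),
                    mechanosensitive=row["mechanosensitive"].strip().lower() == "true",
                    dv12_shift=parse_value(row["dv12_shift"]),
                    notes=row.get("notes", "").strip("-").strip(),
                    source_table="table2",
                )
            )
        except (KeyError, TableParseError) as exc:
            raise TableParseError(f"table2 row {row.get('channel')!r}: {exc}") from exc
    return records


def write_functional_table(
    records: Sequence[FunctionalRecord], path: str | Path
) -> None:
    """Write records back in the fixture dialect (lossless round trip)."""

    def fmt(interval: Interval | None) -> str:
        if interval is None:
            return "n.d."
        lo, hi = interval
        if lo == hi:
            return repr(lo)  # full float precision for a lossless round trip
        return f"{lo!r} to {hi!r}"

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            [
                "channel", "domain", "s3_index", "s3s4_index", "s1s4_index",
                "charge_e0", "q10_act", "q10_inact", "dv12_shift",
                "mechanosensitive", "source_table",
            ]
        )
        for r in records:
            writer.writerow(
                [
                    r.channel,
                    r.domain or "-",
                    "" if r.s3_index is None else f"{r.s3_index:g}",
                    "" if r.s3s4_index is None else f"{r.s3s4_index:g}",
                    "" if r.s1s4_index is None else f"{r.s1s4_index:g}",
                    fmt(r.charge_e0),
                    fmt(r.q10_act),
                    fmt(r.q10_inact),
                    fmt(r.dv12_shift),
                    "" if r.mechanosensitive is None else str(r.mechanosensitive).lower(),
                    r.source_table,
                ]
            )


def read_functional_table(path: str | Path) -> list[FunctionalRecord]:
    """Read a table written by :func:`write_functional_table`."""
    records = []
    for row in _read_fixture_rows(path):
        records.append(
            FunctionalRecord(
                channel=row["channel"],
                domain=None if row["domain"] in ("-", "") else row["domain"],
                s3_index=_parse_float(row["s3_index"]),
                s3s4_index=_parse_float(row["s3s4_index"]),
                s1s4_index=_parse_float(row["s1s4_index"]),
                charge_e0=parse_value(row["charge_e0"]),
                q10_act=parse_value(row["q10_act"]),
                q10_inact=parse_value(row["q10_inact"]),
                dv12_shift=parse_value(row["dv12_shift"]),
                mechanosensitive=(
                    None if row["mechanosensitive"] == ""
                    else row["mechanosensitive"] == "true"
                ),
                source_table=row["source_table"],
            )
        )
    return records


# -------------------------------------------------------------- fitting

def _model(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * np.exp(b / (x + c))


def fit_modified_exponential(
    x: Sequence[float],
    y: Sequence[float],
    start: tuple[float, float, float] | None = None,
) -> FitResult:
    """Nonlinear least-squares fit of ``f(x) = a·exp[b/(x + c)]``.

    ``c`` is bounded below so that ``x + c > 0`` over the data.  With no
    explicit start, the default initialization is a = max(y), c = 1 and
    b from the log-ratio of the two endpoint values, refined over a
    small deterministic multi-start grid; the best (lowest SSres)
    solution is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need at least 4 (x, y) points")
    c_floor = -float(np.min(x)) + 1e-6

    def residuals(params: np.ndarray) -> np.ndarray:
        a, b, c = params
        return _model(x, a, b, c) - y

    starts: list[tuple[float, float, float]]
    if start is not None:
        starts = [start]
    else:
        a0 = float(np.max(y))
        order = np.argsort(x)
        x0, x1 = x[order[0]], x[order[-1]]
        y0, y1 = max(y[order[0]], 1e-12), max(y[order[-1]], 1e-12)
        starts = []
        for c0 in (1.0, 0.5 * (x1 - x0) + 1.0, 2.0 * (x1 - x0) + 1.0):
            denom = 1.0 / (x1 + c0) - 1.0 / (x0 + c0)
            b0 = math.log(y1 / y0) / denom if denom != 0 else 1.0
            starts.extend([(a0, b0, c0), (a0, -b0, c0), (a0, 1.0, c0), (a0, -1.0, c0)])

    best: optimize.OptimizeResult | None = None
    trace: list[str] = []
    for a0, b0, c0 in starts:
        c0 = max(c0, c_floor + 1e-3)
        try:
            sol = optimize.least_squares(
                residuals,
                x0=np.array([a0, b0, c0]),
                bounds=([1e-12, -np.inf, c_floor], [np.inf, np.inf, np.inf]),
                max_nfev=20000,
            )
        except ValueError as exc:
            trace.append(f"start ({a0:.3g},{b0:.3g},{c0:.3g}): {exc}")
            continue
        trace.append(
            f"start ({a0:.3g},{b0:.3g},{c0:.3g}): cost={sol.cost:.6g} "
            f"status={sol.status}"
        )
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitConvergenceError(
            "modified-exponential fit did not converge; trace:\n" + "\n".join(trace)
        )
    a, b, c = best.x
    ss_res = float(np.sum(residuals(best.x) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FitResult(
        a=float(a), b=float(b), c=float(c),
        r_squared=float(min(max(r_squared, 0.0), 1.0)),
        n_points=len(x), ss_res=ss_res,
    )


# --------------------------------------------------- rank correlation

def rank_correlation(
    pairs: Sequence[tuple[float, float]],
    n_montecarlo: int = 10000,
    seed: int = DEFAULT_PERMUTATION_SEED,
) -> tuple[float, float]:
    """Spearman rho with a permutation p-value.

    For n <= 8 the p-value is exact (all n! permutations enumerated);
    above that a seeded Monte-Carlo estimate with ``n_montecarlo``
    draws is used.  Two-sided: p = P(|rho_perm| >= |rho_observed|).
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 complete pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    rho = float(stats.spearmanr(x, y).statistic)
    observed = abs(rho) - 1e-12
    n = len(x)
    if n <= 8:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            r = stats.spearmanr(x, y[list(perm)]).statistic
            count += abs(r) >= observed
            total += 1
        return rho, count / total
    rng = np.random.default_rng(seed)
    count = 0
    y_perm = y.copy()
    for _ in range(n_montecarlo):
        rng.shuffle(y_perm)
        r = stats.spearmanr(x, y_perm).statistic
        count += abs(r) >= observed
    return rho, (count + 1) / (n_montecarlo + 1)


# ------------------------------------------------- class association

@dataclass(frozen=True)
class AssociationResult:
    classes: tuple[str, ...]
    counts: tuple[tuple[int, ...], tuple[int, ...]]  # rows: trait True / False
    p_value: float


def _log_factorial(n: int) -> float:
    return math.lgamma(n + 1)


def _table_log_prob(
    row: Sequence[int], row2: Sequence[int], row_sums: tuple[int, int],
    col_sums: Sequence[int], total: int,
) -> float:
    lp = (
        _log_factorial(row_sums[0]) + _log_factorial(row_sums[1])
        + sum(_log_factorial(c) for c in col_sums)
        - _log_factorial(total)
        - sum(_log_factorial(v) for v in row)
        - sum(_log_factorial(v) for v in row2)
    )
    return lp


def class_association(
    classes: Mapping[str, str],
    trait: Mapping[str, bool],
) -> AssociationResult:
    """Exact test of flexibility class vs a binary trait.

    Builds the 2×k contingency table over the channels present in both
    maps and computes the Fisher-Freeman-Halton exact p-value by full
    enumeration of tables with the observed margins (p = sum of the
    hypergeometric probabilities of all tables at most as probable as
    the observed one).
    """
    keys = sorted(set(classes) & set(trait))
    if not keys:
        raise ValueError("no channels shared between classes and trait")
    labels = tuple(sorted({classes[k] for k in keys}))
    col_sums = [sum(1 for k in keys if classes[k] == lab) for lab in labels]
    if any(c == 0 for c in col_sums):
        raise ValueError("every compared class needs at least one channel")
    row_true = [
        sum(1 for k in keys if classes[k] == lab and trait[k]) for lab in labels
    ]
    row_false = [c - t for c, t in zip(col_sums, row_true)]
    n_true = sum(row_true)
    total = len(keys)
    row_sums = (n_true, total - n_true)

    observed_lp = _table_log_prob(row_true, row_false, row_sums, col_sums, total)
    p = 0.0
    ranges = [range(0, min(n_true, c) + 1) for c in col_sums]
    for combo in itertools.product(*ranges):
        if sum(combo) != n_true:
            continue
        other = [c - v for c, v in zip(col_sums, combo)]
        lp = _table_log_prob(combo, other, row_sums, col_sums, total)
        if lp <= observed_lp + 1e-9:
            p += math.exp(lp)
    return AssociationResult(
        classes=labels,
        counts=(tuple(row_true), tuple(row_false)),
        p_value=min(p, 1.0),
    )


# ------------------------------------------------------- convenience

def s3_index_fit(
    records: Sequence[FunctionalRecord],
    x_variable: str = "rank",
) -> FitResult:
    """Fit the modified exponential to Table-1 S3 indices.

    ``x_variable`` selects the abscissa: ``"rank"`` orders the families
    by decreasing index and fits against rank 1..n (the layout of the
    family-distribution figure); ``"charge"`` fits against the
    gating-charge midpoint of the rows where a charge is reported.
    """
    rows = [r for r in records if r.source_table != "table2" and r.s3_index is not None]
    if x_variable == "rank":
        ys = sorted((r.s3_index for r in rows), reverse=True)
        xs = list(range(1, len(ys) + 1))
    elif x_variable == "charge":
        pairs = [
            (midpoint(r.charge_e0), r.s3_index)
            for r in rows
            if r.charge_e0 is not None
        ]
        xs = [p[0] for p in pairs]
        ys = [p[1] for p in pairs]
    else:
        raise ValueError("x_variable must be 'rank' or 'charge'")
    return fit_modified_exponential(xs, ys)
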