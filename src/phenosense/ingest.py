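"""Logger-file ingestion: dialect registry, format sniffing, tolerant parsing.

Field loggers export delimited text whose layout varies by vendor, firmware
revision, and even by transmission faults: records can gain or lose columns,
or carry garbled fields. The policy here is *quarantine, not repair*: every
physical data record is either accepted into the canonical series table or
recorded in the :class:`~phenosense.types.IngestionReport` with an index and
a message — nothing is silently dropped or patched, so
``accepted + quarantined == total`` always holds.

Two exemplar dialects are built in (vendor layouts are not standardised, so
these are documented stand-ins):

``tower_wide``
    Single-node export, one row per timestamp, one column per channel,
    comma-delimited, two header lines (logger/node identity, then column
    names), sentinel ``-9999`` for missing values.
``wireless_long``
    Multi-node export, one row per reading:
    ``time <TAB> node <TAB> sensor <TAB> reading``, sentinel ``NaN``.

New dialects can be added with :func:`register_dialect`.
"""

from __future__ import annotations

import getpass
import re
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from .types import (
    CHANNELS,
    IngestionReport,
    PhenosenseError,
    empty_series_table,
    make_series_table,
)


class FormatDetectionError(PhenosenseError):
    """Raised when zero or multiple dialects are consistent with a file."""


_WIDE_HEADER_RE = re.compile(
    r"^# phenosense-logger dialect=(?P<dialect>\S+) node=(?P<node>\S+)\s*$"
)


@dataclass(frozen=True)
class LoggerDialect:
    """Description of one logger export layout."""

    name: str
    delimiter: str
    n_header_lines: int
    timestamp_format: str
    layout: str  # "wide" (one column per channel) or "long" (one row per reading)
    channels: tuple  # permitted channel vocabulary (ordered)
    sentinels: tuple  # strings meaning "no reading"

    def __post_init__(self):
        if not self.channels:
            raise PhenosenseError("dialect channel list must be non-empty")
        for s in self.sentinels:
            try:
                float(s)
            except ValueError:
                continue
            # numeric sentinels are allowed (e.g. -9999) but must be
            # distinguishable from plausible readings; leave that to specs
        if self.layout not in ("wide", "long"):
            raise PhenosenseError(f"unknown layout {self.layout!r}")

    # -- writing ----------------------------------------------------------
    def format_table(self, table: pd.DataFrame) -> list[str]:
        """Render a series table as lines in this dialect (no newlines)."""
        if self.layout == "wide":
            return self._format_wide(table)
        return self._format_long(table)

    def _format_wide(self, table: pd.DataFrame) -> list[str]:
        nodes = table["node_id"].unique() if len(table) else ["node0"]
        if len(nodes) > 1:
            raise PhenosenseError(
                f"dialect {self.name!r} is single-node; table has {len(nodes)} nodes"
            )
        node = nodes[0]
        chans = [c for c in CHANNELS if c in set(table["channel"])] or list(
            self.channels
        )
        unknown = set(table["channel"]) - set(self.channels)
        if unknown:
            raise PhenosenseError(
                f"dialect {self.name!r} does not carry channels {sorted(unknown)}"
            )
        lines = [
            f"# phenosense-logger dialect={self.name} node={node}",
            self.delimiter.join(["timestamp"] + chans),
        ]
        if not len(table):
            return lines
        wide = table.pivot_table(
            index="timestamp", columns="channel", values="value", aggfunc="first",
            dropna=False,
        )
        for ts, row in wide.iterrows():
            fields = [ts.strftime(self.timestamp_format)]
            for c in chans:
                v = row.get(c, np.nan)
                fields.append(self.sentinels[0] if pd.isna(v) else repr(float(v)))
            lines.append(self.delimiter.join(fields))
        return lines

    def _format_long(self, table: pd.DataFrame) -> list[str]:
        lines = [self.delimiter.join(["time", "node", "sensor", "reading"])]
        for _, r in table.iterrows():
            v = self.sentinels[0] if pd.isna(r["value"]) else repr(float(r["value"]))
            lines.append(
                self.delimiter.join(
                    [
                        r["timestamp"].strftime(self.timestamp_format),
                        str(r["node_id"]),
                        str(r["channel"]),
                        v,
                    ]
                )
            )
        return lines


_DIALECTS: dict[str, LoggerDialect] = {}


def register_dialect(dialect: LoggerDialect) -> None:
    _DIALECTS[dialect.name] = dialect


def get_dialect(name: str) -> LoggerDialect:
    try:
        return _DIALECTS[name]
    except KeyError:
        raise PhenosenseError(
            f"unknown dialect {name!r}; registered: {sorted(_DIALECTS)}"
        ) from None


def registered_dialects() -> list[str]:
    return sorted(_DIALECTS)


register_dialect(
    LoggerDialect(
        name="tower_wide",
        delimiter=",",
        n_header_lines=2,
        timestamp_format="%Y-%m-%d %H:%M:%S",
        layout="wide",
        channels=CHANNELS,
        sentinels=("-9999",),
    )
)
register_dialect(
    LoggerDialect(
        name="wireless_long",
        delimiter="\t",
        n_header_lines=1,
        timestamp_format="%Y-%m-%dT%H:%M:%S",
        layout="long",
        channels=CHANNELS,
        sentinels=("NaN", "NAN"),
    )
)


def _read_lines(path) -> list[str]:
    with open(path, "r", errors="replace") as fh:
        return [ln.rstrip("\r\n") for ln in fh]


def _try_timestamp(text: str, fmt: str):
    try:
        return datetime.strptime(text.strip(), fmt)
    except ValueError:
        return None


def _dialect_checks(lines: list[str], d: LoggerDialect) -> dict[str, bool]:
    """Run the sniffing checks for one dialect; True = check passed."""
    checks = {"header": False, "column_count": False, "timestamp": False}
    if len(lines) < d.n_header_lines:
        return checks
    if d.layout == "wide":
        m = _WIDE_HEADER_RE.match(lines[0])
        cols = lines[1].split(d.delimiter) if len(lines) > 1 else []
        header_ok = (
            m is not None
            and m.group("dialect") == d.name
            and len(cols) >= 2
            and cols[0] == "timestamp"
            and all(c in d.channels for c in cols[1:])
        )
        checks["header"] = header_ok
        expected_n = len(cols) if header_ok else None
    else:
        checks["header"] = lines[0].split(d.delimiter) == [
            "time", "node", "sensor", "reading",
        ]
        expected_n = 4
    data = [ln for ln in lines[d.n_header_lines:] if ln.strip()]
    if data and expected_n is not None:
        first = data[0].split(d.delimiter)
        checks["column_count"] = len(first) == expected_n
        checks["timestamp"] = _try_timestamp(first[0], d.timestamp_format) is not None
    return checks


def sniff_format(path) -> LoggerDialect:
    """Identify the unique registered dialect consistent with a file.

    Never guesses: zero or multiple fully-consistent dialects raise a
    :class:`FormatDetectionError` whose message lists, per dialect, which
    checks failed.
    """
    lines = _read_lines(path)
    data_lines = [
        ln for i, ln in enumerate(lines) if ln.strip() and not ln.startswith("#")
    ]
    if not any(ln.strip() for ln in lines):
        raise FormatDetectionError(f"{path}: empty file, no data records")

    results = {name: _dialect_checks(lines, d) for name, d in _DIALECTS.items()}
    consistent = [name for name, ch in results.items() if all(ch.values())]
    if len(consistent) == 1:
        return _DIALECTS[consistent[0]]

    def _describe(name):
        failed = [k for k, ok in results[name].items() if not ok]
        return f"{name}: failed {failed}" if failed else f"{name}: consistent"

    detail = "; ".join(_describe(n) for n in sorted(results))
    if len(data_lines) <= 1 and not consistent:
        raise FormatDetectionError(f"{path}: no data records ({detail})")
    kind = "ambiguous" if len(consistent) > 1 else "no fully consistent dialect"
    raise FormatDetectionError(f"{path}: {kind}; near misses: {detail}")


def parse_logger_file(
    path,
    dialect: LoggerDialect | str | None = None,
    user: str | None = None,
    options: dict | None = None,
) -> tuple[pd.DataFrame, IngestionReport]:
    """Parse a logger export into (series table, ingestion report).

    Parsing is total: any file yields a report (worst case all records
    quarantined). Records with the wrong column count, unparseable fields,
    unknown channels, or timestamps that regress within a (node, channel)
    stream are quarantined with an indexed message; missing-value sentinels
    become explicit gap records.
    """
    if dialect is None:
        d = sniff_format(path)
    elif isinstance(dialect, str):
        d = get_dialect(dialect)
    else:
        d = dialect

    try:
        user = user or getpass.getuser()
    except Exception:  # no passwd entry in minimal containers
        user = user or "unknown"
    report = IngestionReport(
        source=str(path),
        dialect=d.name,
        ingested_at=datetime.now().isoformat(timespec="seconds"),
        user=user,
        options=dict(options or {}),
    )

    lines = _read_lines(path)
    header = lines[: d.n_header_lines]
    data = [(i, ln) for i, ln in enumerate(
        ln for ln in lines[d.n_header_lines:] if ln.strip()
    )]

    node_from_header = None
    header_cols: list[str] | None = None
    if d.layout == "wide":
        m = _WIDE_HEADER_RE.match(header[0]) if header else None
        node_from_header = m.group("node") if m else "unknown"
        if len(header) > 1:
            cols = header[1].split(d.delimiter)
            if cols and cols[0] == "timestamp":
                header_cols = cols[1:]
        if header_cols is None:
            header_cols = list(d.channels)

    rows: list[tuple[int, datetime, str, str, float, str]] = []
    # (record idx, ts, node, channel, value, flag)

    def quarantine(idx: int, kind: str, msg: str) -> None:
        report.defects.append((idx, kind, f"record {idx}: {msg}"))
        report.malformed += 1

    for idx, line in data:
        report.total += 1
        fields = [f.strip() for f in line.split(d.delimiter)]
        expected_n = (1 + len(header_cols)) if d.layout == "wide" else 4
        if len(fields) != expected_n:
            kind = "extra column(s)" if len(fields) > expected_n else "missing column(s)"
            quarantine(idx, kind, f"{kind}: expected {expected_n} columns, got {len(fields)}")
            continue
        ts = _try_timestamp(fields[0], d.timestamp_format)
        if ts is None:
            quarantine(idx, "unparseable timestamp",
                       f"cannot parse timestamp {fields[0]!r} with {d.timestamp_format!r}")
            continue

        if d.layout == "wide":
            parsed: list[tuple[str, float, str]] = []
            bad = None
            for col, raw in zip(header_cols, fields[1:]):
                if raw in d.sentinels:
                    parsed.append((col, np.nan, "gap"))
                    continue
                try:
                    parsed.append((col, float(raw), "ok"))
                except ValueError:
                    bad = (col, raw)
                    break
            if bad is not None:
                quarantine(idx, "unparseable value",
                           f"cannot parse value {bad[1]!r} in column {bad[0]!r}")
                continue
            for col, v, fl in parsed:
                rows.append((idx, ts, node_from_header, col, v, fl))
            report.accepted += 1
        else:
            node, channel, raw = fields[1], fields[2], fields[3]
            if channel not in d.channels:
                quarantine(idx, "unknown channel", f"unknown channel {channel!r}")
                continue
            if raw in d.sentinels:
                rows.append((idx, ts, node, channel, np.nan, "gap"))
                report.accepted += 1
                continue
            try:
                v = float(raw)
            except ValueError:
                quarantine(idx, "unparseable value", f"cannot parse value {raw!r}")
                continue
            rows.append((idx, ts, node, channel, v, "ok"))
            report.accepted += 1

    # quarantine records whose timestamp does not advance within a stream
    last_ts: dict[tuple[str, str], datetime] = {}
    bad_records: set[int] = set()
    for idx, ts, node, channel, _, _ in rows:
        if idx in bad_records:
            continue
        key = (node, channel)
        if key in last_ts and ts <= last_ts[key]:
            bad_records.add(idx)
            quarantine(idx, "timestamp regression",
                       f"timestamp {ts} does not advance for {key}")
            report.accepted -= 1
        else:
            last_ts[key] = ts
    rows = [r for r in rows if r[0] not in bad_records]

    if rows:
        table = make_series_table(
            [r[1] for r in rows],
            [r[2] for r in rows],
            [r[3] for r in rows],
            [r[4] for r in rows],
        )
        table["flag"] = pd.array([r[5] for r in rows], dtype="string")
        table = table.sort_values(
            ["node_id", "channel", "timestamp"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        table = empty_series_table()

    report.check()
    return table, report


@dataclass
class MergeResult:
    """Outcome of merging several series tables."""

    table: pd.DataFrame
    conflicts: list = field(default_factory=list)
    # each conflict: dict(timestamp, node_id, channel, kept, dropped)


def merge_tables(tables: list[pd.DataFrame]) -> MergeResult:
    """Union of series tables with first-wins duplicate resolution.

    Duplicate (timestamp, node, channel) keys keep the earlier-ingested
    record; every duplicate is reported as a conflict (even when the values
    agree), never silently averaged.
    """
    if not tables:
        return MergeResult(table=empty_series_table())
    merged = pd.concat(tables, ignore_index=True)
    key = ["timestamp", "node_id", "channel"]
    dup_mask = merged.duplicated(subset=key, keep="first")
    conflicts = []
    if dup_mask.any():
        kept = merged[~dup_mask].set_index(key)["value"]
        for _, r in merged[dup_mask].iterrows():
            k = (r["timestamp"], r["node_id"], r["channel"])
            conflicts.append(
                {
                    "timestamp": r["timestamp"],
                    "node_id": r["node_id"],
                    "channel": r["channel"],
                    "kept": float(kept.loc[k]) if pd.notna(kept.loc[k]) else np.nan,
                    "dropped": r["value"],
                }
            )
    out = (
        merged[~dup_mask]
        .sort_values(["node_id", "channel", "timestamp"], kind="mergesort")
        .reset_index(drop=True)
    )
    return MergeResult(table=out, conflicts=conflicts)
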