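"""Master-worker file-exchange protocol with trigger files and timing.

One analysis-center process and k data-partner processes communicate only
through files dropped in per-node transfer directories.  Every payload file
is written before its zero-byte trigger, so the appearance of a trigger
guarantees a complete payload.  Folder monitoring uses portable polling with
a configurable interval.  Each protocol step is timestamped in four
categories per node — download, compute, upload, transfer — mirroring the
operational-performance accounting of a production distributed network.
"""

from __future__ import annotations

import json
import shutil
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import make_session, partner_compute
from .protocol import (
    INSTRUCTION_STOP,
    ComputationDirective,
    DraError,
    FittedModel,
    ModelSpec,
    Payload,
    PayloadError,
    ProtocolError,
    SiteDataset,
    aggregate_payloads,
    read_payload,
    write_payload,
)

__all__ = [
    "NodeWorkspace",
    "TransferLog",
    "layout_workdir",
    "run_partner",
    "run_center",
    "run_study",
    "summarize_timings",
    "audit_transfer_dirs",
]


@dataclass
class NodeWorkspace:
    """A node's transfer directories and protocol state."""

    node_id: str
    inbox: Path
    outbox: Path
    state: str = "awaiting_directive"

    def __post_init__(self):
        self.inbox = Path(self.inbox)
        self.outbox = Path(self.outbox)
        if self.inbox == self.outbox:
            raise ProtocolError("inbox and outbox must be disjoint")
        self.inbox.mkdir(parents=True, exist_ok=True)
        self.outbox.mkdir(parents=True, exist_ok=True)


def layout_workdir(workdir, site_ids):
    """Create the standard folder layout; returns (center_ws, {site: ws})."""
    workdir = Path(workdir)
    center = NodeWorkspace(
        "center", workdir / "center" / "inbox", workdir / "center" / "outbox"
    )
    partners = {
        sid: NodeWorkspace(
            sid, workdir / "sites" / sid / "inbox",
            workdir / "sites" / sid / "outbox",
        )
        for sid in site_ids
    }
    return center, partners


@dataclass
class TransferLog:
    """Timestamped step records: (node, class, iteration, step, start, end)."""

    records: list = field(default_factory=list)

    def add(self, node: str, node_class: str, iteration: int, step: str,
            start: float, end: float) -> None:
        if end < start:
            raise ValueError("end precedes start")
        self.records.append(
            {
                "node": node,
                "node_class": node_class,
                "iteration": iteration,
                "step": step,
                "start": start,
                "end": end,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def write_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                doc = dict(rec)
                doc["start_iso"] = _iso(rec["start"])
                doc["end_iso"] = _iso(rec["end"])
                fh.write(json.dumps(doc) + "\n")


def _iso(ts: float) -> str:
    import datetime

    return datetime.datetime.fromtimestamp(
        ts, tz=datetime.timezone.utc
    ).isoformat()


def summarize_timings(log: TransferLog) -> pd.DataFrame:
    """Mean and SE of step durations per (node class, step), plus iteration
    and total wall-clock rows."""
    df = log.to_frame()
    if df.empty:
        raise ValueError("transfer log is empty")
    df = df.assign(duration=df["end"] - df["start"])
    rows = []
    for (node_class, step), grp in df.groupby(["node_class", "step"]):
        durations = grp["duration"].to_numpy()
        m = len(durations)
        se = float(np.std(durations, ddof=1) / np.sqrt(m)) if m > 1 else 0.0
        rows.append(
            {
                "node_class": node_class,
                "step": step,
                "mean_s": float(durations.mean()),
                "se_s": se,
                "count": m,
            }
        )
    per_iter = df.groupby("iteration").apply(
        lambda g: g["end"].max() - g["start"].min(), include_groups=False
    )
    m = len(per_iter)
    rows.append(
        {
            "node_class": "overall",
            "step": "iteration",
            "mean_s": float(per_iter.mean()),
            "se_s": float(per_iter.std(ddof=1) / np.sqrt(m)) if m > 1 else 0.0,
            "count": m,
        }
    )
    rows.append(
        {
            "node_class": "overall",
            "step": "total",
            "mean_s": float(df["end"].max() - df["start"].min()),
            "se_s": 0.0,
            "count": 1,
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File naming and transport


def _directive_name(iteration: int) -> str:
    return f"directive_{iteration:04d}.json"


def _payload_name(site_id: str, iteration: int) -> str:
    return f"payload_{site_id}_{iteration:04d}.json"


def _error_name(site_id: str, iteration: int) -> str:
    return f"error_{site_id}_{iteration:04d}.json"


def _trigger(path: Path) -> Path:
    return path.with_name(path.name + ".trigger")


class LocalFolderTransport:
    """Copies files between node folders — the stand-in for a network hop.

    Files are copied before their triggers, preserving the invariant that a
    visible trigger implies a complete payload.  Pluggable: any object with
    the same ``deliver`` signature can replace it.
    """

    def deliver(self, files, dst: Path) -> None:
        dst.mkdir(parents=True, exist_ok=True)
        for f in files:
            shutil.copy2(f, dst / Path(f).name)
        for f in files:
            _trigger(dst / Path(f).name).touch()


def _write_with_trigger(write_fn, path: Path) -> None:
    write_fn(path)
    _trigger(path).touch()


def _wait_for(paths, poll: float, timeout: float, description: str):
    """Block until every trigger in ``paths`` exists."""
    deadline = time.monotonic() + timeout
    pending = [Path(p) for p in paths]
    while True:
        pending = [p for p in pending if not p.exists()]
        if not pending:
            return
        if time.monotonic() > deadline:
            raise ProtocolError(
                f"timeout waiting for {description}: missing "
                f"{[p.name for p in pending]}"
            )
        time.sleep(poll)


# ---------------------------------------------------------------------------
# Partner node


def run_partner(site: SiteDataset, spec: ModelSpec, workdir,
                poll: float = 0.02, timeout: float = 120.0,
                log: TransferLog | None = None,
                transport: LocalFolderTransport | None = None) -> TransferLog:
    """Run one data partner until it receives a stop directive.

    Loops: block on a directive trigger, compute the requested intermediate
    statistics, write the payload then its trigger, transfer both to the
    center, repeat.  No individual-level row ever reaches the outbox.
    """
    workdir = Path(workdir)
    ws = NodeWorkspace(
        site.site_id,
        workdir / "sites" / site.site_id / "inbox",
        workdir / "sites" / site.site_id / "outbox",
    )
    center_inbox = workdir / "center" / "inbox"
    transport = transport or LocalFolderTransport()
    log = log if log is not None else TransferLog()
    seen: set = set()
    while True:
        deadline = time.monotonic() + timeout
        directive = None
        while directive is None:
            t0 = time.time()
            triggers = sorted(ws.inbox.glob("directive_*.json.trigger"))
            fresh = [t for t in triggers if t.name not in seen]
            if fresh:
                trigger = fresh[0]
                seen.add(trigger.name)
                dpath = trigger.with_name(trigger.name[: -len(".trigger")])
                ws.state = "computing"
                try:
                    with open(dpath) as fh:
                        directive = ComputationDirective.from_dict(json.load(fh))
                except (json.JSONDecodeError, PayloadError) as exc:
                    directive = None
                    _emit_error(ws, center_inbox, transport, site.site_id,
                                _iteration_of(dpath), f"malformed directive: {exc}")
                    ws.state = "awaiting_directive"
                    continue
                log.add(site.site_id, "partner", directive.iteration,
                        "download", t0, time.time())
                break
            if time.monotonic() > deadline:
                raise ProtocolError(
                    f"site {site.site_id}: timed out waiting for a directive"
                )
            time.sleep(poll)

        if directive.instruction == INSTRUCTION_STOP:
            ack = ws.outbox / f"ack_{site.site_id}.json"
            with open(ack, "w") as fh:
                json.dump({"schema": "dra-ack/1", "site_id": site.site_id}, fh)
            _trigger(ack).touch()
            transport.deliver([ack], center_inbox)
            ws.state = "done"
            return log

        t0 = time.time()
        try:
            payload = partner_compute(site, spec, directive)
        except DraError as exc:
            _emit_error(ws, center_inbox, transport, site.site_id,
                        directive.iteration, str(exc))
            ws.state = "awaiting_directive"
            continue
        log.add(site.site_id, "partner", directive.iteration, "compute",
                t0, time.time())

        ws.state = "uploading"
        t0 = time.time()
        out = ws.outbox / _payload_name(site.site_id, directive.iteration)
        _write_with_trigger(lambda p: write_payload(payload, p), out)
        t1 = time.time()
        log.add(site.site_id, "partner", directive.iteration, "upload", t0, t1)
        transport.deliver([out], center_inbox)
        log.add(site.site_id, "partner", directive.iteration, "transfer",
                t1, time.time())
        ws.state = "awaiting_directive"


def _iteration_of(path: Path) -> int:
    try:
        return int(path.stem.split("_")[-1])
    except ValueError:
        return -1


def _emit_error(ws: NodeWorkspace, center_inbox: Path,
                transport: LocalFolderTransport, site_id: str,
                iteration: int, message: str) -> None:
    path = ws.outbox / _error_name(site_id, iteration)
    with open(path, "w") as fh:
        json.dump(
            {
                "schema": "dra-error/1",
                "site_id": site_id,
                "iteration": iteration,
                "message": message,
            },
            fh,
        )
    _trigger(path).touch()
    transport.deliver([path], center_inbox)


# ---------------------------------------------------------------------------
# Analysis center


def run_center(spec: ModelSpec, workdir, site_ids, poll: float = 0.02,
               timeout: float = 120.0,
               log: TransferLog | None = None,
               transport: LocalFolderTransport | None = None):
    """Drive the iterative protocol from the analysis center.

    Returns ``(FittedModel, TransferLog)``.  Also writes ``report.json`` and
    ``transfer_log.jsonl`` into the workdir.
    """
    workdir = Path(workdir)
    site_ids = list(site_ids)
    if not site_ids:
        raise ProtocolError("need at least one partner workspace")
    center, partners = layout_workdir(workdir, site_ids)
    transport = transport or LocalFolderTransport()
    log = log if log is not None else TransferLog()
    session = make_session(spec)

    while True:
        directive = session.next_directive()
        if directive is None:
            break
        # upload: materialize the directive in the center outbox
        t0 = time.time()
        dpath = center.outbox / _directive_name(directive.iteration)
        _write_with_trigger(
            lambda p: _dump_json(directive.to_dict(), p), dpath
        )
        t1 = time.time()
        log.add("center", "center", directive.iteration, "upload", t0, t1)
        # transfer: deliver to every partner inbox
        for sid in site_ids:
            transport.deliver([dpath], partners[sid].inbox)
        log.add("center", "center", directive.iteration, "transfer",
                t1, time.time())
        if directive.instruction == INSTRUCTION_STOP:
            break

        # download: wait for all payload (or error) triggers
        t0 = time.time()
        expected = {
            sid: center.inbox / _payload_name(sid, directive.iteration)
            for sid in site_ids
        }
        deadline = time.monotonic() + timeout
        while True:
            missing = []
            errors = []
            for sid, path in expected.items():
                err = center.inbox / _error_name(sid, directive.iteration)
                if _trigger(err).exists():
                    errors.append((sid, err))
                elif not _trigger(path).exists():
                    missing.append(sid)
            if errors:
                sid, err = errors[0]
                with open(err) as fh:
                    msg = json.load(fh).get("message", "unknown")
                raise ProtocolError(
                    f"site {sid} failed at iteration {directive.iteration}: {msg}"
                )
            if not missing:
                break
            if time.monotonic() > deadline:
                status = {
                    sid: ("received" if sid not in missing else "missing")
                    for sid in site_ids
                }
                raise ProtocolError(
                    f"collection timeout at iteration {directive.iteration}; "
                    f"per-node status: {status}"
                )
            time.sleep(poll)
        t1 = time.time()
        log.add("center", "center", directive.iteration, "download", t0, t1)

        # compute: parse, aggregate, absorb
        t0 = time.time()
        payloads = []
        for sid, path in expected.items():
            try:
                payload = read_payload(path)
            except PayloadError as exc:
                raise PayloadError(
                    f"corrupt payload from site {sid} at iteration "
                    f"{directive.iteration}: {exc}"
                ) from exc
            if payload.site_id != sid:
                raise ProtocolError(
                    f"payload file {path.name} claims site {payload.site_id!r}"
                )
            payloads.append(payload)
        session.receive(aggregate_payloads(payloads))
        log.add("center", "center", directive.iteration, "compute",
                t0, time.time())

    model = session.result()
    model.to_json(workdir / "report.json")
    log.write_jsonl(workdir / "transfer_log.jsonl")
    return model, log


def _dump_json(doc: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh)


def run_study(sites, spec: ModelSpec, workdir, poll: float = 0.01,
              timeout: float = 120.0):
    """End-to-end local run: partner threads plus the center in this thread.

    Results are identical to :func:`run_inprocess` (and independent of
    thread scheduling) because the fitted model depends only on payload
    contents, never on timing.
    """
    sites = list(sites)
    log = TransferLog()
    layout_workdir(workdir, [s.site_id for s in sites])
    failures = []

    def _work(site):
        try:
            run_partner(site, spec, workdir, poll=poll, timeout=timeout, log=log)
        except BaseException as exc:  # surfaced after join
            failures.append((site.site_id, exc))

    threads = [
        threading.Thread(target=_work, args=(s,), daemon=True) for s in sites
    ]
    for t in threads:
        t.start()
    try:
        model, _ = run_center(
            spec, workdir, [s.site_id for s in sites], poll=poll,
            timeout=timeout, log=log,
        )
    finally:
        for t in threads:
            t.join(timeout=10.0)
    if failures:
        sid, exc = failures[0]
        raise ProtocolError(f"partner {sid} failed: {exc}") from exc
    return model, log


# ---------------------------------------------------------------------------
# Privacy audit

_ALLOWED_SCHEMAS = {
    "dra-payload/1", "dra-directive/1", "dra-error/1", "dra-ack/1",
}


def audit_transfer_dirs(workdir) -> list:
    """Schema-validate every file in every inbox/outbox.

    Returns a list of violation strings; an empty list certifies that only
    payload/directive/trigger/ack/error documents — no individual-level
    records — ever crossed a node boundary.
    """
    workdir = Path(workdir)
    violations = []
    boxes = list(workdir.glob("center/inbox")) + list(
        workdir.glob("center/outbox")
    ) + list(workdir.glob("sites/*/inbox")) + list(workdir.glob("sites/*/outbox"))
    for box in boxes:
        for path in sorted(box.iterdir()):
            if path.name.endswith(".trigger"):
                if path.stat().st_size != 0:
                    violations.append(f"{path}: trigger file is not empty")
                continue
            try:
                with open(path) as fh:
                    doc = json.load(fh)
            except (json.JSONDecodeError, UnicodeDecodeError):
                violations.append(f"{path}: not a JSON protocol document")
                continue
            schema = doc.get("schema") if isinstance(doc, dict) else None
            if schema not in _ALLOWED_SCHEMAS:
                violations.append(f"{path}: unknown schema {schema!r}")
                continue
            if schema == "dra-payload/1":
                try:
                    read_payload(path)
                except PayloadError as exc:
                    violations.append(f"{path}: invalid payload ({exc})")
    return violations
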