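"""Minimal structured (JSON-lines) run log shared by all pipeline stages."""
from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path


class PipelineLog:
    """Append-only list of structured log records.

    Each record is a flat dict with at least ``stage``, ``level`` and
    ``message`` keys; :meth:`write` serializes one JSON object per line.
    """

    def __init__(self) -> None:
        self.records: list[dict] = []

    def add(self, stage: str, message: str, level: str = "info", **fields) -> None:
        rec = {"stage": stage, "level": level, "message": message}
        rec.update(fields)
        self.records.append(rec)

    def warnings(self) -> list[dict]:
        return [r for r in self.records if r["level"] == "warning"]

    def errors(self) -> list[dict]:
        return [r for r in self.records if r["level"] == "error"]

    def write(self, path) -> None:
        stamp = _dt.datetime.now().isoformat(timespec="seconds")
        with Path(path).open("w", encoding="utf-8") as fh:
            for rec in self.records:
                fh.write(json.dumps({"time": stamp, **rec}) + "\n")
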