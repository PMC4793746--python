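"""Edit-ledger persistence (JSON is canonical; a TSV view is also written)."""

from __future__ import annotations

from pathlib import Path

from ..assembly import EditLedger


def write_ledger(path: str | Path, ledger: EditLedger) -> None:
    path = Path(path)
    path.write_text(ledger.to_json() + "\n")
    path.with_suffix(path.suffix + ".tsv").write_text(ledger.to_tsv())


def read_ledger(path: str | Path) -> EditLedger:
    return EditLedger.from_json(Path(path).read_text())
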