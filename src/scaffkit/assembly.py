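"""Mutable scaffold assembly with a replayable edit ledger.

Internal coordinates are 0-based half-open throughout.  Every mutation
(split / fusion / junction / gap resize / rename / super-scaffolding /
anchoring) appends one record to the :class:`EditLedger`; replaying the
ledger on the original sequences reproduces the edited assembly exactly,
and the same records drive exact coordinate lifting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class AssemblyError(ValueError):
    pass


@dataclass
class LiftedInterval:
    """Image of a source interval in the edited assembly."""

    scaffold: str
    start: int
    end: int
    flipped: bool = False
    flags: tuple[str, ...] = ()


@dataclass
class EditLedger:
    """Append-only, ordered record of assembly edits."""

    records: list[dict] = field(default_factory=list)

    def append(self, op: str, **params) -> dict:
        rec = {"step": len(self.records), "op": op, **params}
        self.records.append(rec)
        return rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[dict]:
        return iter(self.records)

    # -- coordinate lifting ------------------------------------------------

    def lift_interval(self, scaffold: str, start: int, end: int) -> list[LiftedInterval]:
        """Map a 0-based half-open interval through every ledger record.

        Intervals that cross a split boundary come back as several
        fragments; positions inside removed or resized gap regions are
        clamped to the nearest surviving edge and flagged ``gap_clamped``.
        """
        frags = [LiftedInterval(scaffold, start, end)]
        for rec in self.records:
            nxt: list[LiftedInterval] = []
            for fr in frags:
                nxt.extend(_lift_one(rec, fr))
            frags = nxt
        return frags

    def lift_point(self, scaffold: str, pos: int) -> LiftedInterval:
        frags = self.lift_interval(scaffold, pos, pos + 1)
        return frags[0]

    # -- serialisation -----------------------------------------------------

    def to_tsv(self) -> str:
        lines = ["step\top\ttarget\targs\tnew_name"]
        for rec in self.records:
            extra = {k: v for k, v in rec.items() if k not in ("step", "op")}
            target = extra.pop("target", extra.pop("recipient", extra.pop("name", "")))
            new_name = extra.pop("result", extra.pop("children", ""))
            if isinstance(new_name, (list, tuple)):
                new_name = ",".join(new_name)
            lines.append(
                f"{rec['step']}\t{rec['op']}\t{target}\t{json.dumps(extra, sort_keys=True)}\t{new_name}"
            )
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(self.records, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EditLedger":
        return cls(records=json.loads(text))


def _clamp(fr: LiftedInterval, scaffold: str, edge: int) -> LiftedInterval:
    return LiftedInterval(scaffold, edge, edge, fr.flipped, fr.flags + ("gap_clamped",))


def _lift_one(rec: dict, fr: LiftedInterval) -> list[LiftedInterval]:
    op = rec["op"]
    s, e = fr.start, fr.end

    if op == "split":
        if fr.scaffold != rec["target"]:
            return [fr]
        c1, c2 = rec["children"]
        cut_s, cut_e = rec["cut_start"], rec["cut_end"]
        out: list[LiftedInterval] = []
        if s < cut_s:
            out.append(LiftedInterval(c1, s, min(e, cut_s), fr.flipped, fr.flags))
        if e > cut_e:
            out.append(
                LiftedInterval(c2, max(s, cut_e) - cut_e, e - cut_e, fr.flipped, fr.flags)
            )
        if not out:  # entirely inside the trimmed cut region
            if cut_s - s <= e - cut_e or cut_e >= rec["parent_len"]:
                out.append(_clamp(fr, c1, cut_s))
            else:
                out.append(_clamp(fr, c2, 0))
        return out

    if op == "fusion":
        g0, g1 = rec["gap_start"], rec["gap_end"]
        lp, dn = rec["left_pad"], rec["donor_len"]
        if fr.scaffold == rec["donor"]:
            base = g0 + lp
            if rec["orientation"] == "+":
                return [LiftedInterval(rec["recipient"], base + s, base + e, fr.flipped, fr.flags)]
            return [
                LiftedInterval(
                    rec["recipient"], base + dn - e, base + dn - s, not fr.flipped, fr.flags
                )
            ]
        if fr.scaffold == rec["recipient"]:
            delta = lp + dn + rec["right_pad"] - (g1 - g0)
            if e <= g0:
                return [fr]
            if s >= g1:
                return [LiftedInterval(fr.scaffold, s + delta, e + delta, fr.flipped, fr.flags)]
            # overlaps the replaced gap: clamp to nearest edge
            if g0 - s >= e - g1:
                lo = min(s, g0)
                return [LiftedInterval(fr.scaffold, lo, g0, fr.flipped, fr.flags + ("gap_clamped",))]
            return [
                LiftedInterval(
                    fr.scaffold, g1 + delta, max(e, g1) + delta, fr.flipped, fr.flags + ("gap_clamped",)
                )
            ]
        return [fr]

    if op == "junction":
        L = rec["left_len"]
        if fr.scaffold == rec["left"]:
            if rec["left_flip"]:
                return [LiftedInterval(rec["result"], L - e, L - s, not fr.flipped, fr.flags)]
            return [LiftedInterval(rec["result"], s, e, fr.flipped, fr.flags)]
        if fr.scaffold == rec["right"]:
            off = L + rec["gap"]
            R = rec["right_len"]
            if rec["right_flip"]:
                return [
                    LiftedInterval(rec["result"], off + R - e, off + R - s, not fr.flipped, fr.flags)
                ]
            return [LiftedInterval(rec["result"], off + s, off + e, fr.flipped, fr.flags)]
        return [fr]

    if op == "gap_resize":
        if fr.scaffold != rec["target"]:
            return [fr]
        g0, g1 = rec["gap_start"], rec["gap_end"]
        delta = rec["new_length"] - (g1 - g0)
        if e <= g0:
            return [fr]
        if s >= g1:
            return [LiftedInterval(fr.scaffold, s + delta, e + delta, fr.flipped, fr.flags)]
        if s < g0 and e > g1:  # spans the whole gap: stretch with it
            return [LiftedInterval(fr.scaffold, s, e + delta, fr.flipped, fr.flags)]
        if g0 - s >= e - g1:
            return [
                LiftedInterval(fr.scaffold, min(s, g0), g0, fr.flipped, fr.flags + ("gap_clamped",))
                if s >= g0
                else LiftedInterval(fr.scaffold, s, g0, fr.flipped, fr.flags + ("gap_clamped",))
            ]
        return [
            LiftedInterval(
                fr.scaffold, g1 + delta, max(e, g1) + delta, fr.flipped, fr.flags + ("gap_clamped",)
            )
        ]

    if op == "rename":
        new = rec["mapping"].get(fr.scaffold)
        if new is None:
            return [fr]
        return [LiftedInterval(new, s, e, fr.flipped, fr.flags)]

    if op in ("superscaffold", "anchor"):
        objects = rec["objects"] if op == "anchor" else [rec]
        for obj in objects:
            for comp in obj["components"]:
                if comp["id"] == fr.scaffold:
                    off, length = comp["start"], comp["length"]
                    name = obj["name"]
                    if comp["strand"] == "-":
                        return [
                            LiftedInterval(name, off + length - e, off + length - s, not fr.flipped, fr.flags)
                        ]
                    return [LiftedInterval(name, off + s, off + e, fr.flipped, fr.flags)]
        return [fr]

    raise AssemblyError(f"unknown ledger op {op!r}")


@dataclass
class Assembly:
    """Named scaffold sequences plus the ledger of edits applied so far."""

    sequences: dict[str, str]
    ledger: EditLedger = field(default_factory=EditLedger)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "Assembly":
        return cls(sequences={name: seq for name, seq in records})

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)

    def length_of(self, name: str) -> int:
        return len(self.sequences[name])

    def copy(self) -> "Assembly":
        return Assembly(dict(self.sequences), EditLedger(list(self.ledger.records)))

    # -- edit operations ---------------------------------------------------

    def split(self, name: str, pos: int, child_names: tuple[str, str] | None = None) -> tuple[str, str]:
        """Cut ``name`` at ``pos``; an N-run straddling the cut is trimmed
        from both new ends."""
        seq = self.sequences[name]
        if not 0 < pos < len(seq):
            raise AssemblyError(f"split position {pos} out of range for {name} (len {len(seq)})")
        cut_s, cut_e = pos, pos
        while cut_s > 0 and seq[cut_s - 1] == "N":
            cut_s -= 1
        while cut_e < len(seq) and seq[cut_e] == "N":
            cut_e += 1
        if cut_s == 0 or cut_e == len(seq):
            raise AssemblyError(f"split of {name} at {pos} would leave an empty child")
        if child_names is None:
            child_names = (f"{name}.1", f"{name}.2")
        c1, c2 = child_names
        for c in child_names:
            if c in self.sequences:
                raise AssemblyError(f"child name {c} already present")
        new = {}
        for k, v in self.sequences.items():
            if k == name:
                new[c1] = seq[:cut_s]
                new[c2] = seq[cut_e:]
            else:
                new[k] = v
        self.sequences = new
        self.ledger.append(
            "split", target=name, pos=pos, cut_start=cut_s, cut_end=cut_e,
            children=[c1, c2], parent_len=len(seq),
        )
        return c1, c2

    def fuse(self, donor: str, recipient: str, gap_start: int, gap_end: int,
             orientation: str, min_pad: int = 10) -> None:
        """Insert ``donor`` into the N-gap ``[gap_start, gap_end)`` of
        ``recipient``; the residual gap is split evenly on both sides, with
        ``min_pad`` Ns as a floor when the donor overfills the gap."""
        dseq = self.sequences[donor]
        rseq = self.sequences[recipient]
        if set(rseq[gap_start:gap_end]) != {"N"}:
            raise AssemblyError(
                f"fusion target region {recipient}:{gap_start}-{gap_end} is not all N"
            )
        residual = (gap_end - gap_start) - len(dseq)
        if residual < 2 * min_pad:
            left_pad = right_pad = min_pad
        else:
            left_pad = residual // 2
            right_pad = residual - left_pad
        ins = dseq if orientation == "+" else revcomp(dseq)
        self.sequences[recipient] = (
            rseq[:gap_start] + "N" * left_pad + ins + "N" * right_pad + rseq[gap_end:]
        )
        del self.sequences[donor]
        self.ledger.append(
            "fusion", donor=donor, recipient=recipient, gap_start=gap_start,
            gap_end=gap_end, orientation=orientation, left_pad=left_pad,
            right_pad=right_pad, donor_len=len(dseq),
        )

    def join(self, left: str, right: str, left_flip: bool = False,
             right_flip: bool = False, gap: int = 100, result: str | None = None) -> str:
        lseq = self.sequences[left]
        rseq = self.sequences[right]
        if result is None:
            result = left
        if left_flip:
            lseq = revcomp(lseq)
        if right_flip:
            rseq = revcomp(rseq)
        joined = lseq + "N" * gap + rseq
        new = {}
        for k, v in self.sequences.items():
            if k == left:
                new[result] = joined
            elif k != right:
                new[k] = v
        self.sequences = new
        self.ledger.append(
            "junction", left=left, right=right, left_flip=left_flip,
            right_flip=right_flip, gap=gap, result=result,
            left_len=len(lseq), right_len=len(rseq),
        )
        return result

    def resize_gap(self, name: str, gap_start: int, gap_end: int, new_length: int) -> None:
        seq = self.sequences[name]
        if set(seq[gap_start:gap_end]) != {"N"}:
            raise AssemblyError(f"{name}:{gap_start}-{gap_end} is not an N-run")
        self.sequences[name] = seq[:gap_start] + "N" * new_length + seq[gap_end:]
        self.ledger.append(
            "gap_resize", target=name, gap_start=gap_start, gap_end=gap_end,
            new_length=new_length,
        )

    def rename(self, mapping: dict[str, str]) -> None:
        missing = [k for k in mapping if k not in self.sequences]
        if missing:
            raise AssemblyError(f"rename of unknown scaffolds: {missing}")
        values = list(mapping.values())
        if len(set(values)) != len(values):
            raise AssemblyError("rename mapping is not injective")
        clash = [v for v in values if v in self.sequences and v not in mapping]
        if clash:
            raise AssemblyError(f"rename targets already exist: {clash}")
        self.sequences = {mapping.get(k, k): v for k, v in self.sequences.items()}
        self.ledger.append("rename", mapping=dict(mapping))

    def rename_by_length(self, prefix: str = "scaffold") -> dict[str, str]:
        """Rename all scaffolds by decreasing length (ties by old name)."""
        order = sorted(self.sequences, key=lambda k: (-len(self.sequences[k]), k))
        width = max(4, len(str(len(order))))
        mapping = {old: f"{prefix}{i + 1:0{width}d}" for i, old in enumerate(order)}
        # two-phase rename to dodge old/new name collisions
        tmp = {old: f"\x00{i}" for i, old in enumerate(order)}
        self.sequences = {tmp.get(k, k): v for k, v in self.sequences.items()}
        inv = {f"\x00{i}": mapping[old] for i, old in enumerate(order)}
        self.sequences = {inv.get(k, k): v for k, v in self.sequences.items()}
        self.ledger.append("rename", mapping=mapping)
        return mapping

    def superscaffold(self, name: str, components: list[dict]) -> None:
        """Concatenate ``components`` (dicts with id/start/strand/length)
        into a new object, padding between them with Ns."""
        end = 0
        parts: list[str] = []
        for comp in sorted(components, key=lambda c: c["start"]):
            if comp["start"] < end:
                raise AssemblyError(f"superscaffold {name}: overlapping component {comp['id']}")
            parts.append("N" * (comp["start"] - end))
            seq = self.sequences[comp["id"]]
            parts.append(seq if comp["strand"] != "-" else revcomp(seq))
            end = comp["start"] + comp["length"]
        new_seq = "".join(parts)
        for comp in components:
            del self.sequences[comp["id"]]
        self.sequences[name] = new_seq
        self.ledger.append(
            "superscaffold", name=name,
            components=[dict(c) for c in sorted(components, key=lambda c: c["start"])],
            length=len(new_seq),
        )

    def anchor(self, objects: list[dict], keep_unanchored: bool = True) -> None:
        """Replace anchored scaffolds by pseudo-molecule objects.

        ``objects``: list of {name, components: [{id, start, strand, length}]}.
        """
        new: dict[str, str] = {}
        used: set[str] = set()
        for obj in objects:
            end = 0
            parts: list[str] = []
            for comp in obj["components"]:
                if comp["id"] in used:
                    raise AssemblyError(f"scaffold {comp['id']} anchored twice")
                used.add(comp["id"])
                parts.append("N" * (comp["start"] - end))
                seq = self.sequences[comp["id"]]
                parts.append(seq if comp["strand"] != "-" else revcomp(seq))
                end = comp["start"] + comp["length"]
            new[obj["name"]] = "".join(parts)
        if keep_unanchored:
            for k, v in self.sequences.items():
                if k not in used:
                    new[k] = v
        self.sequences = new
        self.ledger.append("anchor", objects=[{
            "name": o["name"], "components": [dict(c) for c in o["components"]],
        } for o in objects])

    # -- replay ------------------------------------------------------------

    @classmethod
    def replay(cls, original: dict[str, str], ledger: EditLedger) -> "Assembly":
        """Re-apply every ledger record to ``original``; the result must be
        byte-identical to the assembly the ledger was recorded on."""
        asm = cls(dict(original))
        for rec in ledger:
            op = rec["op"]
            if op == "split":
                asm.split(rec["target"], rec["pos"], tuple(rec["children"]))
            elif op == "fusion":
                asm.fuse(rec["donor"], rec["recipient"], rec["gap_start"],
                         rec["gap_end"], rec["orientation"])
            elif op == "junction":
                asm.join(rec["left"], rec["right"], rec["left_flip"],
                         rec["right_flip"], rec["gap"], rec["result"])
            elif op == "gap_resize":
                asm.resize_gap(rec["target"], rec["gap_start"], rec["gap_end"],
                               rec["new_length"])
            elif op == "rename":
                asm.rename(rec["mapping"])
            elif op == "superscaffold":
                asm.superscaffold(rec["name"], rec["components"])
            elif op == "anchor":
                asm.anchor(rec["objects"])
            else:
                raise AssemblyError(f"unknown ledger op {op!r}")
        asm.ledger = EditLedger(list(ledger.records))
        return asm

    def base_multiset(self) -> dict[str, int]:
        """Strand-symmetric non-N base counts over the whole assembly.

        A+T and C+G are pooled because edits may reverse-complement a
        component; the double-stranded content is the edit invariant.
        """
        counts = {"AT": 0, "CG": 0}
        for seq in self.sequences.values():
            counts["AT"] += seq.count("A") + seq.count("T")
            counts["CG"] += seq.count("C") + seq.count("G")
        return counts
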