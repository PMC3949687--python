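"""A deliberately small coding-HGVS grammar and consequence classifier.

The panel operates in transcript space, so variant identity and consequence
are derived from the HGVS c./p. strings themselves — no reference genome is
consulted.  The grammar covers the forms that occur on targeted recessive-
deafness panels:

* substitutions ``c.1477C>T``, including intronic offsets ``c.5821-2A>G``;
* deletions / duplications / insertions with or without ranges
  (``c.1623dup``, ``c.3567delG``, ``c.6205_6206delAT``,
  ``c.4482_4483insTG``, ``c.5780_5781delCT``).

Anything outside the grammar raises :class:`HgvsParseError` naming the
offending token rather than guessing.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .models import FRAMESHIFT, MISSENSE, NONSENSE, OTHER, SPLICE, UsherdxError

__all__ = ["CodingChange", "HgvsParseError", "parse_coding", "classify_consequence"]


class HgvsParseError(UsherdxError):
    """Raised when an HGVS string falls outside the supported grammar."""


_SUB = re.compile(
    r"^c\.(?P<pos>\d+)(?P<offset>[+-]\d+)?(?P<ref>[ACGTacgt])>(?P<alt>[ACGTacgt])$"
)
_INDEL = re.compile(
    r"^c\.(?P<start>\d+)(?P<offset1>[+-]\d+)?"
    r"(?:_(?P<end>\d+)(?P<offset2>[+-]\d+)?)?"
    r"(?P<kind>delins|del|dup|ins)(?P<seq>[ACGTacgt]*)$"
)

# Amino acids: three-letter (capitalised) or one-letter codes; stop written
# as X, Ter or *.
_AA = r"(?:[A-Z][a-z]{2}|[A-Z])"
_P_SUB = re.compile(
    rf"^p\.(?:\()?(?P<ref>{_AA})(?P<pos>\d+)(?P<alt>{_AA}|X|Ter|\*)(?:\))?$"
)


@dataclass(frozen=True)
class CodingChange:
    """Parsed coding-DNA change."""

    raw: str
    kind: str  # "sub" | "del" | "dup" | "ins" | "delins"
    start: int
    end: int
    intron_offset: int  # 0 for exonic positions
    ref: str = ""
    alt: str = ""
    seq: str = ""

    @property
    def length_change(self) -> int:
        """Net inserted (+) or deleted (-) bases; 0 for substitutions."""
        span = self.end - self.start + 1
        if self.kind == "sub":
            return 0
        if self.kind == "del":
            return -(len(self.seq) or span)
        if self.kind == "dup":
            return len(self.seq) or span
        if self.kind == "ins":
            return len(self.seq) or 1
        # delins: replacement length minus span
        return len(self.seq) - span


def parse_coding(hgvs_c: str) -> CodingChange:
    """Parse a coding HGVS string within the supported grammar."""
    token = "".join(hgvs_c.split())
    m = _SUB.match(token)
    if m:
        return CodingChange(
            raw=token,
            kind="sub",
            start=int(m.group("pos")),
            end=int(m.group("pos")),
            intron_offset=int(m.group("offset") or 0),
            ref=m.group("ref").upper(),
            alt=m.group("alt").upper(),
        )
    m = _INDEL.match(token)
    if m:
        start = int(m.group("start"))
        end = int(m.group("end") or start)
        if end < start:
            raise HgvsParseError(f"range end before start in {token!r}")
        kind = m.group("kind")
        if kind == "ins" and not m.group("seq") and end == start:
            raise HgvsParseError(f"insertion without sequence or range: {token!r}")
        return CodingChange(
            raw=token,
            kind=kind,
            start=start,
            end=end,
            intron_offset=int(m.group("offset1") or 0),
            seq=m.group("seq").upper(),
        )
    raise HgvsParseError(f"unsupported HGVS coding token {token!r}")


def _protein_substitution(hgvs_p: str) -> Optional[re.Match]:
    if not hgvs_p:
        return None
    return _P_SUB.match("".join(hgvs_p.split()))


def classify_consequence(hgvs_c: str, hgvs_p: str = "", location: str = "") -> str:
    """Classify a variant as missense / nonsense / frameshift / splice / other.

    Decision rules, in order:

    1. *splice* — the coding change sits at an intronic offset within the
       canonical +/-2 splice dinucleotides (e.g. ``c.5821-2A>G``);
    2. *frameshift* — the protein change contains ``fs``, or the coding
       change alters length by a non-multiple of three;
    3. *nonsense* — a substitution whose protein change ends in a stop
       (X / Ter / ``*``);
    4. *missense* — a substitution replacing a single residue with a
       different residue;
    5. *other* — everything else (in-frame indels, synonymous changes,
       deep-intronic substitutions).

    The classification is deterministic; an unparseable ``hgvs_c`` raises
    :class:`HgvsParseError`.
    """
    change = parse_coding(hgvs_c)
    p = "".join(hgvs_p.split()) if hgvs_p else ""

    if change.intron_offset != 0 and abs(change.intron_offset) <= 2:
        return SPLICE
    if "fs" in p.lower():
        return FRAMESHIFT
    if change.kind != "sub" and change.length_change % 3 != 0:
        return FRAMESHIFT
    if change.kind == "sub":
        m = _protein_substitution(p)
        if m:
            alt = m.group("alt")
            if alt in ("X", "Ter", "*"):
                return NONSENSE
            if alt != m.group("ref"):
                return MISSENSE
    return OTHER
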