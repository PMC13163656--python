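"""Fixed-length 5-bit binary encoding of amino-acid sequences ("genetic images").

Each residue letter is mapped to a 5-bit code by alphabetic index (A=1 ...
Z=26, pad ``-`` = 0), so a protein of L residues becomes a bit vector of
length 5*L. Sequences are first fitted to reference lengths (the human
cytochrome b and COI lengths by default) by end-padding with ``-`` or
end-truncation — no alignment is performed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ResidueAlphabet",
    "ReferenceLengths",
    "OrganismRecord",
    "GeneticImage",
    "BITS_PER_RESIDUE",
    "residue_code",
    "fit_to_reference",
    "build_genetic_image",
    "decode_image",
    "render_image",
]

BITS_PER_RESIDUE = 5

MODES = ("concat", "cytb", "coi")


def _default_code_map() -> dict[str, int]:
    codes = {"-": 0}
    for i, letter in enumerate(string.ascii_uppercase, start=1):
        codes[letter] = i
    return codes


@dataclass(frozen=True)
class ResidueAlphabet:
    """Residue letters with their 5-bit integer codes.

    The default maps ``A``..``Z`` to 1..26 and the pad character ``-`` to 0;
    every code fits in 5 bits.
    """

    code_of: dict[str, int] = field(default_factory=_default_code_map)
    pad_symbol: str = "-"

    def __post_init__(self) -> None:
        values = list(self.code_of.values())
        if len(set(values)) != len(values):
            raise ValueError("alphabet codes must be injective")
        if self.code_of.get(self.pad_symbol) != 0:
            raise ValueError("pad symbol must map to code 0")
        if any(not (0 <= v < 2**BITS_PER_RESIDUE) for v in values):
            raise ValueError("every code must fit in 5 bits")

    @property
    def symbols(self) -> list[str]:
        return sorted(self.code_of, key=self.code_of.get)

    def symbol_of(self, code: int) -> str:
        for sym, c in self.code_of.items():
            if c == code:
                return sym
        raise ValueError(f"unknown 5-bit code {code:05b}")


@dataclass(frozen=True)
class ReferenceLengths:
    """Residue counts the two barcode proteins are fitted to.

    Defaults are the human cytochrome b (380) and COI (513) lengths.
    """

    cytb_len: int = 380
    coi_len: int = 513

    def __post_init__(self) -> None:
        if self.cytb_len <= 0 or self.coi_len <= 0:
            raise ValueError("reference lengths must be strictly positive")

    def length_for(self, mode: str) -> int:
        if mode == "concat":
            return self.cytb_len + self.coi_len
        if mode == "cytb":
            return self.cytb_len
        if mode == "coi":
            return self.coi_len
        raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class OrganismRecord:
    """One organism's names and its two barcode-protein sequences."""

    common_name: str
    latin_name: str
    cytb_seq: str
    coi_seq: str

    def __post_init__(self) -> None:
        if not self.cytb_seq or not self.coi_seq:
            raise ValueError(f"{self.latin_name}: sequences must be nonempty")
        object.__setattr__(self, "cytb_seq", self.cytb_seq.upper())
        object.__setattr__(self, "coi_seq", self.coi_seq.upper())


@dataclass(frozen=True)
class GeneticImage:
    """A fixed-length bit vector encoding one organism in one mode."""

    organism_id: str
    mode: str
    bits: np.ndarray
    residue_len: int

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 1 or bits.size != BITS_PER_RESIDUE * self.residue_len:
            raise ValueError(
                f"bit vector must have length {BITS_PER_RESIDUE * self.residue_len}, "
                f"got {bits.size}"
            )
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("bits must be 0/1")
        object.__setattr__(self, "bits", bits)

    def to_bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)


def residue_code(symbol: str, alphabet: ResidueAlphabet | None = None) -> str:
    """Return the 5-bit code (e.g. ``'00001'`` for alanine) of one residue.

    Case-insensitive; the pad ``-`` encodes as ``'00000'``. Unknown symbols
    raise ``ValueError`` naming the offending character.
    """
    alphabet = alphabet or ResidueAlphabet()
    sym = symbol.upper()
    if sym not in alphabet.code_of:
        raise ValueError(f"unknown residue symbol {symbol!r}")
    return format(alphabet.code_of[sym], f"0{BITS_PER_RESIDUE}b")


def fit_to_reference(seq: str, target_len: int, pad_symbol: str = "-") -> str:
    """Fit a residue string to an exact length by end-padding or truncation."""
    if target_len <= 0:
        raise ValueError("target_len must be positive")
    if len(seq) >= target_len:
        return seq[:target_len]
    return seq + pad_symbol * (target_len - len(seq))


def _encode_residues(seq: str, alphabet: ResidueAlphabet) -> np.ndarray:
    bits = np.zeros(BITS_PER_RESIDUE * len(seq), dtype=np.uint8)
    for i, sym in enumerate(seq.upper()):
        if sym not in alphabet.code_of:
            raise ValueError(f"unknown residue symbol {sym!r} at position {i}")
        code = alphabet.code_of[sym]
        for j in range(BITS_PER_RESIDUE):
            bits[BITS_PER_RESIDUE * i + j] = (code >> (BITS_PER_RESIDUE - 1 - j)) & 1
    return bits


def fitted_sequence(record: OrganismRecord, ref: ReferenceLengths, mode: str) -> str:
    """The residue string that a genetic image in this mode encodes."""
    if mode == "concat":
        return fit_to_reference(record.cytb_seq, ref.cytb_len) + fit_to_reference(
            record.coi_seq, ref.coi_len
        )
    if mode == "cytb":
        return fit_to_reference(record.cytb_seq, ref.cytb_len)
    if mode == "coi":
        return fit_to_reference(record.coi_seq, ref.coi_len)
    raise ValueError(f"unknown mode {mode!r}")


def build_genetic_image(
    record: OrganismRecord,
    ref: ReferenceLengths | None = None,
    mode: str = "concat",
    alphabet: ResidueAlphabet | None = None,
) -> GeneticImage:
    """Encode one organism as a genetic image.

    In ``concat`` mode cytochrome b comes first, then COI, each fitted to its
    reference length; the result has 5 x (cytb_len + coi_len) bits (4465 with
    the default human reference lengths).
    """
    ref = ref or ReferenceLengths()
    alphabet = alphabet or ResidueAlphabet()
    seq = fitted_sequence(record, ref, mode)
    return GeneticImage(
        organism_id=record.latin_name,
        mode=mode,
        bits=_encode_residues(seq, alphabet),
        residue_len=ref.length_for(mode),
    )


def decode_image(image: GeneticImage, alphabet: ResidueAlphabet | None = None) -> str:
    """Recover the residue string from a genetic image (round trip of encode)."""
    alphabet = alphabet or ResidueAlphabet()
    bits = image.bits
    if bits.size % BITS_PER_RESIDUE:
        raise ValueError("bit length not divisible by 5")
    out = []
    for i in range(bits.size // BITS_PER_RESIDUE):
        group = bits[BITS_PER_RESIDUE * i : BITS_PER_RESIDUE * (i + 1)]
        code = int("".join(map(str, group)), 2)
        out.append(alphabet.symbol_of(code))
    return "".join(out)


def default_palette(alphabet: ResidueAlphabet | None = None) -> dict[str, tuple[int, int, int]]:
    """A deterministic distinct color per symbol (pad is black)."""
    alphabet = alphabet or ResidueAlphabet()
    palette: dict[str, tuple[int, int, int]] = {}
    for sym, code in alphabet.code_of.items():
        if code == 0:
            palette[sym] = (0, 0, 0)
        else:
            # spread hues over the 26 letters; fixed formula keeps renders stable
            r = (code * 37) % 200 + 55
            g = (code * 91) % 200 + 55
            b = (code * 53) % 200 + 55
            palette[sym] = (r, g, b)
    return palette


def render_image(
    image: GeneticImage,
    path: str,
    palette: dict[str, tuple[int, int, int]] | None = None,
    layout: tuple[int, int] | None = None,
    cell_size: int = 4,
    alphabet: ResidueAlphabet | None = None,
) -> None:
    """Write a PNG with one colored cell per residue (a debugging aid).

    ``layout`` is (rows, cols); rows*cols must cover residue_len. Default is a
    near-square grid. Identical sequences give byte-identical files.
    """
    from PIL import Image as PILImage

    alphabet = alphabet or ResidueAlphabet()
    palette = palette or default_palette(alphabet)
    seq = decode_image(image, alphabet)
    n = len(seq)
    if layout is None:
        cols = int(np.ceil(np.sqrt(n)))
        rows = int(np.ceil(n / cols))
    else:
        rows, cols = layout
    if rows * cols < n:
        raise ValueError(f"layout {rows}x{cols} cannot hold {n} residues")
    canvas = np.zeros((rows, cols, 3), dtype=np.uint8)
    for i, sym in enumerate(seq):
        canvas[i // cols, i % cols] = palette[sym]
    canvas = np.repeat(np.repeat(canvas, cell_size, axis=0), cell_size, axis=1)
    PILImage.fromarray(canvas, mode="RGB").save(path, format="PNG")
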