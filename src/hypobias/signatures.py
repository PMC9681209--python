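"""Gene signatures: GMT I/O and the astrocyte composite signature builder.

The astrocyte composite signature (ACS) is the deduplicated union of several
published astrocyte gene sets merged into one list; the builder is generic
over its component sets, so the shipped component lists can be swapped for
any GMT the user prefers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources


@dataclass(frozen=True)
class GeneSignature:
    """A named, non-empty, duplicate-free gene set."""

    name: str
    genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")

    def __len__(self):
        return len(self.genes)

    def __contains__(self, gene):
        return gene in self.genes


def read_gmt(path_or_buf) -> list[GeneSignature]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    sigs = []
    for line in lines:
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sigs.append(GeneSignature(parts[0], [g for g in parts[2:] if g]))
    return sigs


def write_gmt(sigs, path) -> None:
    with open(path, "w") as fh:
        for sig in sigs:
            fh.write("\t".join([sig.name, "na", *sorted(sig.genes)]) + "\n")


def build_acs(component_sigs, name: str = "ACS") -> GeneSignature:
    """Merge component astrocyte signatures into one composite set (union,
    deduplicated). An empty component list is an error."""
    comps = list(component_sigs)
    if not comps:
        raise ValueError("no component signatures supplied")
    genes = frozenset().union(*(s.genes for s in comps))
    return GeneSignature(name, genes)


def _load_packaged(fname: str) -> list[GeneSignature]:
    ref = resources.files("hypobias.data").joinpath(fname)
    with ref.open() as fh:
        return read_gmt(fh)


def astrocyte_components() -> list[GeneSignature]:
    """The six packaged astrocyte component signatures.

    These are synthetic stand-ins built from canonical astrocyte marker
    symbols (see the data file header name suffix); replace with curated
    lists via :func:`read_gmt` for real analyses.
    """
    return _load_packaged("astrocyte_components.synthetic.gmt")


def opc_signatures() -> list[GeneSignature]:
    """The two packaged OPC signatures (synthetic stand-ins; see above)."""
    return _load_packaged("opc_signatures.synthetic.gmt")


def default_acs() -> GeneSignature:
    return build_acs(astrocyte_components())
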