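"""ATP cost accounting for peptide signal synthesis.

The signal peptide is expensive: it is translated as a long propeptide,
then processed to a short mature peptide carrying an isoprenyl
modification.  The ledger used here charges

* the biosynthesis cost of the residues retained in the mature peptide
  (ATP equivalents per amino acid, standard aerobic values);
* the polymerization cost of the full precursor, (precursor length - 1)
  peptide bonds at 4 ATP per bond (2 ATP for aminoacyl-tRNA charging
  counted as two high-energy bonds, 2 GTP in elongation) — translation
  cost is paid for every residue even though most of the propeptide is
  cleaved away, while the cleaved residues' biosynthesis cost is assumed
  recycled;
* each post-translational modification at its configured ATP price
  (geranylation: 30 ATP, two isoprene units at ~15 ATP each).

For the ComX-168 decapeptide (ADPITRQWGD, 55-residue precursor,
geranylated tryptophan) this totals 484 ATP per molecule — three orders
of magnitude above the ~8 ATP of a short acyl-homoserine lactone, which
is why the nanomolar operating range of this system matters.

Costs and the reference peptide ship as editable YAML configuration
(``qscomm/data/comx168.yaml``); nothing is hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import DomainError

__all__ = ["PeptideSpec", "CostTable", "atp_cost", "load_config", "comx168"]


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide to be costed.

    sequence : one-letter residue codes of the *mature* peptide (the
        residues whose biosynthesis is charged).
    precursor_length : residue count of the translated precursor (the
        peptide bonds that are charged); defaults to the mature length.
    modifications : (name, ATP cost) pairs.
    """

    sequence: str
    precursor_length: int | None = None
    modifications: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DomainError("sequence must be non-empty")
        length = self.precursor_length if self.precursor_length is not None else len(self.sequence)
        if length < len(self.sequence):
            raise DomainError("precursor cannot be shorter than the mature peptide")
        for name, cost in self.modifications:
            if cost < 0:
                raise DomainError(f"modification {name!r} has negative cost")

    @property
    def bonds(self) -> int:
        length = self.precursor_length if self.precursor_length is not None else len(self.sequence)
        return length - 1


@dataclass(frozen=True)
class CostTable:
    """Residue -> ATP biosynthesis cost, plus the per-bond polymerization cost."""

    residue_costs: dict[str, float]
    bond_cost: float

    def __post_init__(self) -> None:
        if self.bond_cost < 0 or any(c < 0 for c in self.residue_costs.values()):
            raise DomainError("all costs must be non-negative")


def atp_cost(spec: PeptideSpec, table: CostTable) -> float:
    """Total ATP per molecule: residues + precursor bonds + modifications."""
    missing = sorted({r for r in spec.sequence if r not in table.residue_costs})
    if missing:
        raise DomainError(f"cost table does not cover residue(s): {', '.join(missing)}")
    residues = sum(table.residue_costs[r] for r in spec.sequence)
    mods = sum(cost for _, cost in spec.modifications)
    return residues + spec.bonds * table.bond_cost + mods


def load_config(path: str | Path | None = None) -> tuple[PeptideSpec, CostTable]:
    """Load a (PeptideSpec, CostTable) pair from YAML.

    With no path, loads the packaged ComX-168 configuration.
    """
    if path is None:
        text = resources.files("qscomm.data").joinpath("comx168.yaml").read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    pep = cfg["peptide"]
    spec = PeptideSpec(
        sequence=pep["sequence"],
        precursor_length=pep.get("precursor_length"),
        modifications=tuple((m["name"], float(m["atp"])) for m in pep.get("modifications", [])),
    )
    table = CostTable(
        residue_costs={str(k): float(v) for k, v in cfg["residue_costs_atp"].items()},
        bond_cost=float(cfg["bond_cost_atp"]),
    )
    return spec, table


def comx168() -> tuple[PeptideSpec, CostTable]:
    """The packaged ComX pherotype-168 specification and cost table."""
    return load_config(None)
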