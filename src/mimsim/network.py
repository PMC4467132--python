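"""Data model, validation and (de)serialization for MIM-style kinetic networks.

A network is a list of species (basic proteins, modified forms, complexes,
inhibitors and mRNAs) together with reversible binding reactions and
catalytic (enzyme-driven) conversions.  Every non-mRNA species carries a
*composition*: the multiset of basic-protein moieties it contains.  The
composition is the backbone of the two structural checks the package relies
on everywhere:

* moiety balance — a reaction may rearrange moieties between species but
  never create or destroy them;
* moiety totals — the total concentration of a basic protein summed over
  all its forms and complexes, which is conserved along any trajectory of a
  closed model.

Concentrations are in nM, time in seconds, bimolecular rate constants in
1/(nM*s).
"""

from __future__ import annotations

import copy as _copy
import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

__all__ = [
    "SpeciesDecl",
    "ReversibleReaction",
    "CatalyticReaction",
    "RateProcess",
    "NetworkModel",
    "ModelFormatError",
    "ModelValidationError",
    "load_model",
    "write_model",
    "expand_rate_processes",
    "moiety_totals",
]

Role = Literal["basic", "modified", "complex", "inhibitor", "mRNA"]

ROLES = ("basic", "modified", "complex", "inhibitor", "mRNA")


class ModelFormatError(ValueError):
    """A file could not be parsed in the requested format."""


class ModelValidationError(ValueError):
    """A model violates a structural invariant (ids, references, balance)."""


def _as_multiset(composition: Mapping[str, int] | Iterable[str]) -> dict[str, int]:
    if isinstance(composition, Mapping):
        return {k: int(v) for k, v in composition.items() if int(v) != 0}
    out: dict[str, int] = {}
    for k in composition:
        out[k] = out.get(k, 0) + 1
    return out


@dataclass
class SpeciesDecl:
    """One chemical species of the network.

    Parameters
    ----------
    id : unique token used in reactions.
    name : free-text label.
    role : one of ``basic``, ``modified``, ``complex``, ``inhibitor``, ``mRNA``.
    composition : multiset of basic-protein ids contained in this species.
        A basic protein contains itself; a phospho-form contains its basic
        protein; a complex contains the union.  Empty only for mRNAs.
    initial_concentration : nM, non-negative.
    """

    id: str
    name: str = ""
    role: Role = "basic"
    composition: dict[str, int] = field(default_factory=dict)
    initial_concentration: float = 0.0

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.id
        self.composition = _as_multiset(self.composition)
        if self.role == "basic" and not self.composition:
            self.composition = {self.id: 1}
        if self.role not in ROLES:
            raise ModelValidationError(f"species {self.id!r}: unknown role {self.role!r}")
        if self.role != "mRNA" and not self.composition:
            raise ModelValidationError(
                f"species {self.id!r}: composition must be non-empty for role {self.role!r}"
            )
        if self.initial_concentration < 0:
            raise ModelValidationError(
                f"species {self.id!r}: negative initial concentration"
            )


@dataclass
class ReversibleReaction:
    """A + B <=> AB (or unimolecular A <=> A').

    ``kon`` is the forward rate constant (1/s unimolecular, 1/(nM*s)
    bimolecular), ``koff`` the reverse (same convention on the product side).
    """

    id: str
    reactants: list[str] = field(default_factory=list)
    products: list[str] = field(default_factory=list)
    kon: float = 0.0
    koff: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= len(self.reactants) <= 2):
            raise ModelValidationError(
                f"reaction {self.id!r}: needs 1-2 reactants, got {len(self.reactants)}"
            )
        if not (1 <= len(self.products) <= 2):
            raise ModelValidationError(
                f"reaction {self.id!r}: needs 1-2 products, got {len(self.products)}"
            )
        if self.kon < 0 or self.koff < 0:
            raise ModelValidationError(f"reaction {self.id!r}: negative rate constant")


@dataclass
class CatalyticReaction:
    """enzyme-driven substrate -> product conversion.

    ``law`` is ``mass_action`` (v = kcat*[E]*[S], kcat in 1/(nM*s)) or
    ``michaelis_menten`` (v = kcat*[E]*[S]/(Km+[S]), kcat in 1/s, Km in nM).
    Catalysis converts forms: substrate and product must share one
    composition, and the enzyme is unchanged.
    """

    id: str
    enzyme: str = ""
    substrate: str = ""
    product: str = ""
    kcat: float = 0.0
    law: Literal["mass_action", "michaelis_menten"] = "mass_action"
    Km: float | None = None

    def __post_init__(self) -> None:
        if self.kcat < 0:
            raise ModelValidationError(f"reaction {self.id!r}: negative kcat")
        if self.law not in ("mass_action", "michaelis_menten"):
            raise ModelValidationError(f"reaction {self.id!r}: unknown law {self.law!r}")
        if self.law == "michaelis_menten":
            if self.Km is None or self.Km <= 0:
                raise ModelValidationError(
                    f"reaction {self.id!r}: michaelis_menten requires Km > 0"
                )


@dataclass(frozen=True)
class RateProcess:
    """One directed rate process (the unit the network-size bookkeeping counts)."""

    id: str
    kind: Literal["forward", "reverse", "catalytic"]
    source: str  # id of the reaction it came from


@dataclass
class NetworkModel:
    """A validated, simulatable MIM-style reaction network.

    ``annotations`` is a free-form (JSON-serializable) map; the engine and
    readout layers recognise these keys:

    * ``readouts``: moiety -> {"active": [species ids counted as the
      phosphorylated/active form]}
    * ``active_forms``: moiety -> species id of its "active" form (used by
      constitutive-activation directives)
    * ``mrna``: gene name -> mRNA species id
    """

    species: list[SpeciesDecl] = field(default_factory=list)
    reversible: list[ReversibleReaction] = field(default_factory=list)
    catalytic: list[CatalyticReaction] = field(default_factory=list)
    annotations: dict = field(default_factory=dict)
    promoter: "object | None" = None  # PromoterConfig, attached by callers

    # -- structure ---------------------------------------------------------
    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def species_by_id(self) -> dict[str, SpeciesDecl]:
        return {s.id: s for s in self.species}

    def moiety_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.species:
            for m in s.composition:
                seen.setdefault(m, None)
        return list(seen)

    def copy(self) -> "NetworkModel":
        out = _copy.deepcopy(self)
        return out

    # -- validation --------------------------------------------------------
    def validate(self) -> "NetworkModel":
        """Check id uniqueness, reference integrity and moiety balance.

        Returns self so calls can be chained; raises ModelValidationError
        listing every offending reaction otherwise.
        """
        ids = [s.id for s in self.species]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ModelValidationError(f"duplicate species ids: {sorted(dupes)}")
        known = set(ids)
        comp = {s.id: s.composition for s in self.species}

        problems: list[str] = []
        rids = [r.id for r in self.reversible] + [c.id for c in self.catalytic]
        rdupes = {i for i in rids if rids.count(i) > 1}
        if rdupes:
            problems.append(f"duplicate reaction ids: {sorted(rdupes)}")

        def total(sids: Iterable[str]) -> dict[str, int]:
            t: dict[str, int] = {}
            for sid in sids:
                for m, n in comp.get(sid, {}).items():
                    t[m] = t.get(m, 0) + n
            return t

        for r in self.reversible:
            missing = [s for s in (*r.reactants, *r.products) if s not in known]
            if missing:
                problems.append(f"reaction {r.id!r}: unknown species {missing}")
                continue
            if total(r.reactants) != total(r.products):
                problems.append(
                    f"reaction {r.id!r}: moiety balance fails "
                    f"({total(r.reactants)} != {total(r.products)})"
                )
        for c in self.catalytic:
            missing = [s for s in (c.enzyme, c.substrate, c.product) if s not in known]
            if missing:
                problems.append(f"reaction {c.id!r}: unknown species {missing}")
                continue
            if comp[c.substrate] != comp[c.product]:
                problems.append(
                    f"reaction {c.id!r}: substrate/product composition differs "
                    f"({comp[c.substrate]} != {comp[c.product]})"
                )
        if problems:
            raise ModelValidationError("; ".join(problems))
        return self


# ---------------------------------------------------------------------------
# operations


def expand_rate_processes(model: NetworkModel) -> list[RateProcess]:
    """Expand reactions into directed rate processes.

    Each reversible reaction contributes a forward and a reverse process,
    each catalytic reaction a single one, so the process count is
    2*|reversible| + |catalytic|.
    """
    out: list[RateProcess] = []
    for r in model.reversible:
        out.append(RateProcess(f"{r.id}:fwd", "forward", r.id))
        out.append(RateProcess(f"{r.id}:rev", "reverse", r.id))
    for c in model.catalytic:
        out.append(RateProcess(f"{c.id}:cat", "catalytic", c.id))
    return out


def moiety_totals(
    model: NetworkModel, state: Mapping[str, float] | None = None
) -> dict[str, float]:
    """Total concentration per basic-protein moiety.

    Sums, for each moiety, concentration over every species whose
    composition contains it (counting multiplicity).  With ``state`` given
    (species id -> concentration) totals are computed there instead of at
    the declared initial concentrations.
    """
    totals: dict[str, float] = {m: 0.0 for m in model.moiety_ids()}
    for s in model.species:
        conc = s.initial_concentration if state is None else float(state.get(s.id, 0.0))
        for m, n in s.composition.items():
            totals[m] += n * conc
    return totals


# ---------------------------------------------------------------------------
# native tabular format: a directory with species.csv + reactions.csv
# (+ optional annotations.json)

_SPECIES_COLS = ["id", "name", "role", "composition", "initial_concentration"]
_REACTION_COLS = [
    "id", "type", "reactants", "products", "kon", "koff",
    "enzyme", "substrate", "product", "law", "kcat", "Km",
]


def _comp_to_str(comp: Mapping[str, int]) -> str:
    return "+".join(
        m if n == 1 else f"{n}*{m}" for m, n in sorted(comp.items())
    )


def _comp_from_str(text: str, where: str) -> dict[str, int]:
    comp: dict[str, int] = {}
    text = text.strip()
    if not text:
        return comp
    for part in text.split("+"):
        part = part.strip()
        if not part:
            raise ModelFormatError(f"{where}: empty composition term")
        if "*" in part:
            n, _, m = part.partition("*")
            try:
                comp[m.strip()] = comp.get(m.strip(), 0) + int(n)
            except ValueError as exc:
                raise ModelFormatError(f"{where}: bad composition term {part!r}") from exc
        else:
            comp[part] = comp.get(part, 0) + 1
    return comp


def _write_native(model: NetworkModel, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "species.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_SPECIES_COLS)
        for s in model.species:
            w.writerow(
                [s.id, s.name, s.role, _comp_to_str(s.composition),
                 repr(s.initial_concentration)]
            )
    with open(path / "reactions.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_REACTION_COLS)
        for r in model.reversible:
            w.writerow(
                [r.id, "reversible", "+".join(r.reactants), "+".join(r.products),
                 repr(r.kon), repr(r.koff), "", "", "", "", "", ""]
            )
        for c in model.catalytic:
            w.writerow(
                [c.id, "catalytic", "", "", "", "", c.enzyme, c.substrate,
                 c.product, c.law, repr(c.kcat), "" if c.Km is None else repr(c.Km)]
            )
    if model.annotations:
        (path / "annotations.json").write_text(
            json.dumps(model.annotations, indent=1), encoding="utf-8"
        )


def _read_native(path: Path) -> NetworkModel:
    sp_file = path / "species.csv"
    rx_file = path / "reactions.csv"
    if not sp_file.exists() or not rx_file.exists():
        raise ModelFormatError(
            f"native model directory {path} must contain species.csv and reactions.csv"
        )
    species: list[SpeciesDecl] = []
    with open(sp_file, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            where = f"species.csv row {i + 2} (id={row.get('id')!r})"
            try:
                species.append(
                    SpeciesDecl(
                        id=row["id"],
                        name=row.get("name") or row["id"],
                        role=row.get("role") or "basic",
                        composition=_comp_from_str(row.get("composition", ""), where),
                        initial_concentration=float(row.get("initial_concentration") or 0),
                    )
                )
            except (KeyError, ValueError, ModelValidationError) as exc:
                raise ModelFormatError(f"{where}: {exc}") from exc
    reversible: list[ReversibleReaction] = []
    catalytic: list[CatalyticReaction] = []
    with open(rx_file, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            where = f"reactions.csv row {i + 2} (id={row.get('id')!r})"
            try:
                kind = row["type"]
                if kind == "reversible":
                    reversible.append(
                        ReversibleReaction(
                            id=row["id"],
                            reactants=[s for s in row["reactants"].split("+") if s],
                            products=[s for s in row["products"].split("+") if s],
                            kon=float(row["kon"]),
                            koff=float(row["koff"]),
                        )
                    )
                elif kind == "catalytic":
                    km = row.get("Km", "")
                    catalytic.append(
                        CatalyticReaction(
                            id=row["id"],
                            enzyme=row["enzyme"],
                            substrate=row["substrate"],
                            product=row["product"],
                            law=row.get("law") or "mass_action",
                            kcat=float(row["kcat"]),
                            Km=float(km) if km else None,
                        )
                    )
                else:
                    raise ModelFormatError(f"{where}: unknown reaction type {kind!r}")
            except (KeyError, ValueError, ModelValidationError) as exc:
                raise ModelFormatError(f"{where}: {exc}") from exc
    annotations: dict = {}
    ann_file = path / "annotations.json"
    if ann_file.exists():
        annotations = json.loads(ann_file.read_text(encoding="utf-8"))
    model = NetworkModel(
        species=species, reversible=reversible, catalytic=catalytic,
        annotations=annotations,
    )
    return model.validate()


def load_model(path: str | Path, format: str = "native_table") -> NetworkModel:
    """Read and validate a NetworkModel from disk.

    ``format`` is ``native_table`` (a directory with species.csv and
    reactions.csv) or ``sbml`` (a single Level-3 XML file).  Units are the
    package convention: nM and seconds.
    """
    path = Path(path)
    if format == "native_table":
        return _read_native(path)
    if format == "sbml":
        from . import sbml as _sbml

        return _sbml.read_sbml(path).validate()
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: NetworkModel, path: str | Path, format: str = "native_table") -> None:
    """Write a validated model to disk in the named format."""
    model.validate()
    path = Path(path)
    if format == "native_table":
        _write_native(model, path)
        return
    if format == "sbml":
        from . import sbml as _sbml

        _sbml.write_sbml(model, path)
        return
    raise ValueError(f"unknown model format {format!r}")
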