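"""PDB-format reader and writer (wwPDB v3.3 fixed columns).

The reader consumes ATOM/HETATM/TER/MODEL/ENDMDL/CRYST1/TITLE/HEADER
records from a text stream.  ATOM records of standard residues populate
polymeric chains; HETATM records (and waters, whatever their record type)
populate non-polymeric chains.  Unknown record types are skipped and
counted.  The writer refuses to truncate: any field that does not fit the
fixed columns raises :class:`PdbOverflowError`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional, TextIO, Union

from .model import (Atom, Chain, CrystalCell, Entity, Group, Structure,
                    group_category, three_to_one, AMINO_ACIDS_3, NUCLEOTIDES)

__all__ = ["read_pdb", "write_pdb", "ParserOptions", "PdbParseError",
           "PdbOverflowError"]


class PdbParseError(ValueError):
    """Malformed PDB content; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class PdbOverflowError(ValueError):
    """A field does not fit the fixed PDB columns."""


@dataclass
class ParserOptions:
    """Options shared by the PDB and mmCIF readers.

    ``model_index``: parse only this model (0-based); None keeps all models.
    ``keep_alt_locs``: keep every alternate location; default keeps only the
    first-listed alt-loc per atom name.  ``parse_header``: read title/cell
    metadata.
    """

    model_index: Optional[int] = None
    keep_alt_locs: bool = False
    parse_header: bool = True

    def __post_init__(self):
        if self.model_index is not None and self.model_index < 0:
            raise ValueError("model_index must be >= 0")


def _as_stream(source: Union[str, TextIO]) -> TextIO:
    if isinstance(source, str):
        if "\n" in source or source.lstrip().startswith(
                ("ATOM", "HETATM", "HEADER", "MODEL", "CRYST1", "TITLE",
                 "REMARK", "data_")):
            return io.StringIO(source)
        return open(source, "r", encoding="ascii", errors="strict")
    return source


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return ""
    stripped = name.lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "ZN",
                                                       "MG", "MN", "NA", "SE"):
        return stripped[:2].upper()
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int) -> dict:
    if len(line.rstrip("\n")) < 54:
        raise PdbParseError("ATOM/HETATM record shorter than coordinate "
                            "columns (needs 54)", lineno)
    try:
        return {
            "record": line[0:6].strip(),
            "serial": int(line[6:11]),
            "name": line[12:16].strip(),
            "alt_loc": line[16].strip(),
            "res_name": line[17:20].strip(),
            "chain_id": line[21].strip(),
            "res_seq": int(line[22:26]),
            "ins_code": line[26].strip(),
            "x": float(line[30:38]),
            "y": float(line[38:46]),
            "z": float(line[46:54]),
            "occupancy": float(line[54:60]) if line[54:60].strip() else 1.0,
            "b_factor": float(line[60:66]) if line[60:66].strip() else 0.0,
            "element": line[76:78].strip() if len(line) >= 78 else "",
        }
    except ValueError as exc:
        raise PdbParseError(f"cannot parse ATOM/HETATM fields ({exc})",
                            lineno) from None


def _parse_cryst1(line: str, lineno: int) -> tuple[CrystalCell, Optional[str]]:
    if len(line.rstrip("\n")) < 54:
        raise PdbParseError("CRYST1 record too short", lineno)
    try:
        cell = CrystalCell(float(line[6:15]), float(line[15:24]),
                           float(line[24:33]), float(line[33:40]),
                           float(line[40:47]), float(line[47:54]))
    except ValueError as exc:
        raise PdbParseError(f"bad CRYST1 record ({exc})", lineno) from None
    sg = line[55:66].strip() if len(line) > 55 else ""
    return cell, sg or None


class _ModelBuilder:
    """Accumulates atom records of one model into typed chains."""

    def __init__(self, keep_alt_locs: bool):
        self.keep_alt_locs = keep_alt_locs
        # (auth_id, kind) -> Chain; kind in {poly, het, water}
        self.chains: dict[tuple[str, str], Chain] = {}
        self.order: list[tuple[str, str]] = []

    def add(self, rec: dict) -> None:
        category = group_category(rec["res_name"])
        if category == "water":
            kind = "water"
        elif category in ("amino_acid", "nucleotide") and \
                rec["record"] == "ATOM":
            kind = "poly"
        else:
            kind = "het"
        key = (rec["chain_id"], kind)
        chain = self.chains.get(key)
        if chain is None:
            chain = Chain(rec["chain_id"],
                          chain_type=(Chain.POLYMERIC if kind == "poly"
                                      else Chain.NON_POLYMERIC))
            self.chains[key] = chain
            self.order.append(key)
        group = None
        for g in reversed(chain.groups):
            if (g.seq_id_auth == rec["res_seq"]
                    and g.ins_code == rec["ins_code"]
                    and g.res_name == rec["res_name"]):
                group = g
                break
        if group is None:
            group = Group(rec["res_name"], rec["res_seq"], rec["ins_code"],
                          category=category)
            chain.add_group(group)
        element = rec["element"] or _guess_element(rec["name"])
        atom = Atom(rec["serial"], rec["name"], element,
                    (rec["x"], rec["y"], rec["z"]), rec["alt_loc"],
                    rec["occupancy"], rec["b_factor"],
                    rec["record"] == "HETATM")
        group.add_atom(atom, keep_alt_locs=self.keep_alt_locs)

    def finish(self) -> list[Chain]:
        return [self.chains[k] for k in self.order]


def _assign_label_asym_ids(models: list[list[Chain]]) -> None:
    """Give every chain of the first model a distinct label asym id;
    polymeric chains keep their author id when unique."""
    used: set[str] = set()
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    pool = list(alphabet) + [a + b for a in alphabet for b in alphabet]
    idx = 0
    for model in models:
        used_model: set[str] = set()
        for chain in model:
            cand = chain.auth_id if (chain.is_polymeric
                                     and chain.auth_id) else None
            if cand is None or cand in used_model:
                while pool[idx % len(pool)] in used_model or \
                        pool[idx % len(pool)] in {c.auth_id for c in model}:
                    idx += 1
                cand = pool[idx % len(pool)]
                idx += 1
            chain.asym_id = cand
            used_model.add(cand)
        used |= used_model


def _synthesize_entities(models: list[list[Chain]]) -> list[Entity]:
    """Build entities from chain contents when the file carries none."""
    entities: list[Entity] = []
    poly_by_seq: dict[str, int] = {}
    het_by_name: dict[str, int] = {}
    water_entity: Optional[int] = None
    next_id = 1
    for chain in models[0]:
        if chain.is_polymeric:
            seq = chain.sequence
            eid = poly_by_seq.get(seq)
            if eid is None:
                eid = next_id
                next_id += 1
                poly_by_seq[seq] = eid
                is_aa = any(g.category == "amino_acid" for g in chain.groups)
                entities.append(Entity(eid, "polymer", "polymer entity",
                                       seq, "protein" if is_aa else "other"))
            chain.entity_id = eid
        else:
            cats = {g.category for g in chain.groups}
            if cats == {"water"}:
                if water_entity is None:
                    water_entity = next_id
                    next_id += 1
                    entities.append(Entity(water_entity, "water", "water"))
                chain.entity_id = water_entity
            else:
                name = "/".join(sorted({g.res_name for g in chain.groups
                                        if g.category != "water"}))
                eid = het_by_name.get(name)
                if eid is None:
                    eid = next_id
                    next_id += 1
                    het_by_name[name] = eid
                    entities.append(Entity(eid, "non-polymer", name))
                chain.entity_id = eid
    for model in models[1:]:
        by_auth = {(c.auth_id, c.chain_type): c for c in models[0]}
        for chain in model:
            ref = by_auth.get((chain.auth_id, chain.chain_type))
            if ref is not None:
                chain.entity_id = ref.entity_id
    return entities


def read_pdb(source: Union[str, TextIO],
             options: Optional[ParserOptions] = None) -> Structure:
    """Parse a PDB-format stream, file path, or literal text."""
    options = options or ParserOptions()
    stream = _as_stream(source)
    structure = Structure(models=[])
    builder = _ModelBuilder(options.keep_alt_locs)
    models: list[list[Chain]] = []
    model_count = 0
    in_wanted_model = options.model_index in (None, 0)
    explicit_models = False
    n_skipped = 0
    title_parts: list[str] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        record = line[:6].strip()
        if record == "MODEL":
            explicit_models = True
            if builder.chains:
                models.append(builder.finish())
                builder = _ModelBuilder(options.keep_alt_locs)
            in_wanted_model = (options.model_index is None
                               or options.model_index == model_count)
            model_count += 1
        elif record == "ENDMDL":
            if builder.chains:
                models.append(builder.finish())
                builder = _ModelBuilder(options.keep_alt_locs)
        elif record in ("ATOM", "HETATM"):
            if in_wanted_model:
                builder.add(_parse_atom_line(line, lineno))
        elif record == "CRYST1":
            if options.parse_header:
                # wwPDB placeholder cells (1,1,1,90,90,90 P 1) are kept:
                # still formally valid and needed for round-trips
                structure.cell, structure.space_group_name = \
                    _parse_cryst1(line, lineno)
        elif record == "TITLE":
            if options.parse_header:
                title_parts.append(line[10:].rstrip())
        elif record == "HEADER":
            if options.parse_header and len(line) >= 66:
                structure.struct_id = line[62:66].strip()
        elif record in ("TER", "END", "ANISOU", "SEQRES", "REMARK", "CONECT",
                        "MASTER", "SCALE1", "SCALE2", "SCALE3", "ORIGX1",
                        "ORIGX2", "ORIGX3", "COMPND", "SOURCE", "KEYWDS",
                        "EXPDTA", "AUTHOR", "REVDAT", "JRNL", "SEQADV",
                        "DBREF", "HELIX", "SHEET", "SSBOND", "LINK", "CISPEP",
                        "SITE", "FORMUL", "HET", "HETNAM", "HETSYN", "MTRIX1",
                        "MTRIX2", "MTRIX3", "MODRES", "CAVEAT", "OBSLTE",
                        "SPRSDE", "SPLIT", "NUMMDL"):
            pass
        else:
            n_skipped += 1
    if builder.chains:
        models.append(builder.finish())
    if not models:
        if explicit_models and options.model_index is not None:
            raise PdbParseError(
                f"model index {options.model_index} not present", 0)
        models = [[]]
    structure.models = models
    structure.title = " ".join(p.strip() for p in title_parts).strip()
    _assign_label_asym_ids(models)
    structure.entities = _synthesize_entities(models)
    return structure


def _format_atom_name(name: str, element: str) -> str:
    if len(name) > 4:
        raise PdbOverflowError(f"atom name {name!r} exceeds 4 characters")
    if len(name) == 4:
        return name
    # single-letter elements start in column 14
    if len(element) == 1 or element == "":
        return f" {name:<3s}"
    return f"{name:<4s}"


def _check_writable(structure: Structure) -> None:
    for model in structure.models:
        for chain in model:
            if len(chain.auth_id) > 1:
                raise PdbOverflowError(
                    f"chain id {chain.auth_id!r} does not fit the single "
                    f"PDB chain-id column")
            for g in chain.groups:
                if len(g.res_name) > 3:
                    raise PdbOverflowError(
                        f"residue name {g.res_name!r} exceeds 3 characters")
                if not -999 <= g.seq_id_auth <= 9999:
                    raise PdbOverflowError(
                        f"residue number {g.seq_id_auth} out of PDB range")
                for a in g.atoms:
                    if a.serial > 99999:
                        raise PdbOverflowError(
                            f"atom serial {a.serial} exceeds 99999")


def write_pdb(structure: Structure) -> str:
    """Serialize to PDB format; raises PdbOverflowError on unrepresentable
    fields (never silently truncates)."""
    _check_writable(structure)
    lines: list[str] = []
    if structure.title:
        lines.append(f"TITLE     {structure.title}")
    if structure.cell is not None:
        c = structure.cell
        sg = structure.space_group_name or "P 1"
        lines.append(
            f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
            f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} {sg:<11s}")
    multi = len(structure.models) > 1
    for mi, model in enumerate(structure.models, start=1):
        if multi:
            lines.append(f"MODEL     {mi:4d}")
        for chain in model:
            for g in chain.groups:
                record = ("ATOM  " if chain.is_polymeric
                          and g.category in ("amino_acid", "nucleotide")
                          else "HETATM")
                for a in g.atoms:
                    x, y, z = a.coords
                    for v in (x, y, z):
                        if not -999.999 <= v <= 9999.999:
                            raise PdbOverflowError(
                                f"coordinate {v} does not fit %8.3f")
                    lines.append(
                        f"{record}{a.serial:5d} "
                        f"{_format_atom_name(a.name, a.element)}"
                        f"{a.alt_loc or ' '}"
                        f"{g.res_name:>3s} {chain.auth_id or ' '}"
                        f"{g.seq_id_auth:4d}{g.ins_code or ' '}   "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}"
                        f"{a.occupancy:6.2f}{a.b_factor:6.2f}"
                        f"          {a.element:>2s}")
            if chain.is_polymeric and chain.groups:
                last = chain.groups[-1]
                lines.append(
                    f"TER   {chain.atoms[-1].serial + 1:5d}      "
                    f"{last.res_name:>3s} {chain.auth_id or ' '}"
                    f"{last.seq_id_auth:4d}{last.ins_code or ' '}")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"
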