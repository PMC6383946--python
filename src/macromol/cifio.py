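"""PDBx/mmCIF reader and writer.

A minimal CIF 1.1 tokenizer (key-value pairs, ``loop_`` tables, single- and
double-quoted strings, semicolon text fields, comments) feeding a mapper
for the categories this toolkit consumes: ``atom_site``, ``cell``,
``symmetry``, ``entity``, ``entity_poly`` and ``struct``.  Other categories
are parsed tolerantly and ignored.
"""

from __future__ import annotations

import io
import re
from typing import Optional, TextIO, Union

from .model import (Atom, Chain, CrystalCell, Entity, Group, Structure,
                    group_category)
from .pdbio import ParserOptions, _guess_element

__all__ = ["read_mmcif", "write_mmcif", "CifParseError"]


class CifParseError(ValueError):
    """Malformed CIF content; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


# ---------------------------------------------------------------------------
# tokenizer

def _tokenize(stream: TextIO):
    """Yield (token, line_number) pairs; quoting resolved, comments dropped."""
    lines = stream.read().splitlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        if line.startswith(";"):
            # semicolon text field: runs to the next line starting with ';'
            start = i
            parts = [line[1:]]
            i += 1
            while i < n and not lines[i].startswith(";"):
                parts.append(lines[i])
                i += 1
            if i >= n:
                raise CifParseError("unterminated semicolon text field",
                                    start + 1)
            yield ("\n".join(parts), start + 1)
            i += 1
            continue
        pos = 0
        ln = i + 1
        length = len(line)
        while pos < length:
            ch = line[pos]
            if ch in " \t":
                pos += 1
                continue
            if ch == "#":
                break
            if ch in "'\"":
                quote = ch
                end = pos + 1
                while True:
                    end = line.find(quote, end)
                    if end == -1:
                        raise CifParseError("unterminated quoted string", ln)
                    # closing quote must be followed by whitespace or EOL
                    if end + 1 >= length or line[end + 1] in " \t":
                        break
                    end += 1
                yield (line[pos + 1:end], ln)
                pos = end + 1
            else:
                end = pos
                while end < length and line[end] not in " \t":
                    end += 1
                yield (line[pos:end], ln)
                pos = end
        i += 1


_TAG_RE = re.compile(r"^_([^.\s]+)\.(\S+)$")


def _parse_cif_blocks(stream: TextIO) -> dict[str, dict[str, list]]:
    """First data block -> {category: {item: [values]}} (case-preserving)."""
    categories: dict[str, dict[str, list]] = {}
    tokens = _tokenize(stream)
    pending: list[tuple[str, int]] = []

    def next_token():
        if pending:
            return pending.pop()
        return next(tokens, None)

    seen_data_block = False
    while True:
        tk = next_token()
        if tk is None:
            break
        token, ln = tk
        low = token.lower()
        if low.startswith("data_"):
            if seen_data_block:
                break  # only the first block
            seen_data_block = True
            continue
        if low == "loop_":
            # header tags
            tags: list[tuple[str, str]] = []
            while True:
                tk = next_token()
                if tk is None:
                    raise CifParseError("loop_ without values", ln)
                token2, ln2 = tk
                m = _TAG_RE.match(token2)
                if m:
                    tags.append((m.group(1), m.group(2)))
                else:
                    pending.append((token2, ln2))
                    break
            if not tags:
                raise CifParseError("loop_ without item tags", ln)
            cols: list[list] = [[] for _ in tags]
            count = 0
            while True:
                tk = next_token()
                if tk is None:
                    break
                token2, ln2 = tk
                low2 = token2.lower()
                if (low2 in ("loop_", "stop_") or low2.startswith("data_")
                        or _TAG_RE.match(token2)):
                    pending.append((token2, ln2))
                    break
                cols[count % len(tags)].append(token2)
                count += 1
            if count % len(tags) != 0:
                raise CifParseError(
                    f"loop_ row incomplete: {count} values for "
                    f"{len(tags)} columns", ln)
            for (cat, item), col in zip(tags, cols):
                categories.setdefault(cat, {})[item] = col
            continue
        m = _TAG_RE.match(token)
        if m:
            tk = next_token()
            if tk is None:
                raise CifParseError(f"tag {token} has no value", ln)
            value, _ = tk
            categories.setdefault(m.group(1), {})[m.group(2)] = [value]
            continue
        if low in ("stop_", "global_") or low.startswith("save_"):
            continue
        raise CifParseError(f"unexpected token {token!r}", ln)
    return categories


def _opt(value: Optional[str]) -> Optional[str]:
    if value is None or value in (".", "?"):
        return None
    return value


def _col(cat: dict[str, list], item: str, n: int) -> list[Optional[str]]:
    vals = cat.get(item)
    if vals is None:
        return [None] * n
    return [_opt(v) for v in vals]


# ---------------------------------------------------------------------------
# reader

def read_mmcif(source: Union[str, TextIO],
               options: Optional[ParserOptions] = None) -> Structure:
    """Parse a PDBx/mmCIF stream, file path, or literal text."""
    options = options or ParserOptions()
    if isinstance(source, str):
        if "\n" in source or source.lstrip().startswith(("data_", "#")):
            stream: TextIO = io.StringIO(source)
        else:
            stream = open(source, "r", encoding="ascii", errors="strict")
    else:
        stream = source
    cats = _parse_cif_blocks(stream)
    if "atom_site" not in cats:
        raise CifParseError("no atom_site category found", 0)
    site = cats["atom_site"]
    n = max(len(v) for v in site.values())

    structure = Structure(models=[])
    if options.parse_header:
        if "struct" in cats:
            structure.title = _opt(cats["struct"].get("title", [None])[0]) or ""
            structure.struct_id = \
                _opt(cats["struct"].get("entry_id", [None])[0]) or ""
        if "cell" in cats:
            c = cats["cell"]
            try:
                vals = [float(_opt(c[k][0]))
                        for k in ("length_a", "length_b", "length_c",
                                  "angle_alpha", "angle_beta", "angle_gamma")]
                structure.cell = CrystalCell(*vals)
            except (KeyError, TypeError, ValueError):
                structure.cell = None
        if "symmetry" in cats:
            structure.space_group_name = _opt(
                cats["symmetry"].get("space_group_name_H-M", [None])[0])

    entities: dict[int, Entity] = {}
    if "entity" in cats:
        ent = cats["entity"]
        ne = max(len(v) for v in ent.values())
        ids = _col(ent, "id", ne)
        types = _col(ent, "type", ne)
        descs = _col(ent, "pdbx_description", ne)
        for i in range(ne):
            if ids[i] is None:
                continue
            eid = int(ids[i])
            etype = (types[i] or "polymer").lower()
            if etype not in ("polymer", "non-polymer", "water"):
                etype = "non-polymer"
            entities[eid] = Entity(eid, etype, descs[i] or "")
    if "entity_poly" in cats:
        ep = cats["entity_poly"]
        np_ = max(len(v) for v in ep.values())
        ids = _col(ep, "entity_id", np_)
        ptypes = _col(ep, "type", np_)
        seqs = _col(ep, "pdbx_seq_one_letter_code", np_)
        for i in range(np_):
            if ids[i] is None or int(ids[i]) not in entities:
                continue
            e = entities[int(ids[i])]
            seq = (seqs[i] or "").replace("\n", "").replace(" ", "")
            e.one_letter_sequence = seq
            pt = (ptypes[i] or "").lower()
            if "polypeptide" in pt:
                e.polymer_type = "protein"
            elif "deoxyribo" in pt:
                e.polymer_type = "dna"
            elif "ribo" in pt:
                e.polymer_type = "rna"
            else:
                e.polymer_type = "other"

    group_pdb = _col(site, "group_PDB", n)
    serial = _col(site, "id", n)
    type_symbol = _col(site, "type_symbol", n)
    atom_id = _col(site, "label_atom_id", n)
    alt_id = _col(site, "label_alt_id", n)
    comp_id = _col(site, "label_comp_id", n)
    asym_id = _col(site, "label_asym_id", n)
    entity_col = _col(site, "label_entity_id", n)
    seq_id = _col(site, "label_seq_id", n)
    ins = _col(site, "pdbx_PDB_ins_code", n)
    xs = _col(site, "Cartn_x", n)
    ys = _col(site, "Cartn_y", n)
    zs = _col(site, "Cartn_z", n)
    occ = _col(site, "occupancy", n)
    bf = _col(site, "B_iso_or_equiv", n)
    auth_seq = _col(site, "auth_seq_id", n)
    auth_comp = _col(site, "auth_comp_id", n)
    auth_asym = _col(site, "auth_asym_id", n)
    model_num = _col(site, "pdbx_PDB_model_num", n)

    models: list[list[Chain]] = []
    chain_map: dict[tuple[int, str], Chain] = {}
    model_ids: list[int] = []
    kept_models: list[int] = []
    for i in range(n):
        mnum = int(model_num[i]) if model_num[i] is not None else 1
        if mnum not in model_ids:
            model_ids.append(mnum)
        midx = model_ids.index(mnum)
        if options.model_index is not None and midx != options.model_index:
            continue
        if midx not in kept_models:
            kept_models.append(midx)
            models.append([])
        mslot = kept_models.index(midx)
        if atom_id[i] is None or comp_id[i] is None or xs[i] is None:
            raise CifParseError(
                f"atom_site row {i + 1} lacks a mandatory item", 0)
        label_asym = asym_id[i] or "A"
        auth = auth_asym[i] if auth_asym[i] is not None else label_asym
        res_name = auth_comp[i] or comp_id[i]
        category = group_category(res_name)
        eid = int(entity_col[i]) if entity_col[i] is not None else None
        ent = entities.get(eid) if eid is not None else None
        if ent is not None:
            polymeric = ent.entity_type == "polymer"
        else:
            polymeric = (category in ("amino_acid", "nucleotide")
                         and (group_pdb[i] or "ATOM") == "ATOM")
        key = (mslot, label_asym)
        chain = chain_map.get(key)
        if chain is None:
            chain = Chain(auth, asym_id=label_asym, entity_id=eid,
                          chain_type=(Chain.POLYMERIC if polymeric
                                      else Chain.NON_POLYMERIC))
            chain_map[key] = chain
            models[mslot].append(chain)
        res_seq = (int(auth_seq[i]) if auth_seq[i] is not None
                   else (int(seq_id[i]) if seq_id[i] is not None else 1))
        ins_code = ins[i] or ""
        group = None
        for g in reversed(chain.groups):
            if (g.seq_id_auth == res_seq and g.ins_code == ins_code
                    and g.res_name == res_name):
                group = g
                break
        if group is None:
            group = Group(res_name, res_seq, ins_code,
                          seq_id_label=(int(seq_id[i])
                                        if seq_id[i] is not None else None),
                          category=category)
            chain.add_group(group)
        element = type_symbol[i] or _guess_element(atom_id[i])
        try:
            atom = Atom(int(serial[i]) if serial[i] is not None else i + 1,
                        atom_id[i], element,
                        (float(xs[i]), float(ys[i]), float(zs[i])),
                        alt_id[i] or "",
                        float(occ[i]) if occ[i] is not None else 1.0,
                        float(bf[i]) if bf[i] is not None else 0.0,
                        (group_pdb[i] or "ATOM") == "HETATM")
        except ValueError as exc:
            raise CifParseError(f"atom_site row {i + 1}: {exc}", 0) from None
        group.add_atom(atom, keep_alt_locs=options.keep_alt_locs)
    if not models:
        models = [[]]
    structure.models = models
    if entities:
        structure.entities = sorted(entities.values(),
                                    key=lambda e: e.entity_id)
        # fill polymer sequences from chains when entity_poly was absent
        for chain in models[0]:
            if chain.is_polymeric and chain.entity_id is not None:
                e = entities.get(chain.entity_id)
                if e is not None and not e.one_letter_sequence:
                    e.one_letter_sequence = chain.sequence
                    if e.polymer_type == "none":
                        e.polymer_type = "protein"
    else:
        from .pdbio import _synthesize_entities
        structure.entities = _synthesize_entities(models)
    return structure


# ---------------------------------------------------------------------------
# writer

def _quote(value: Optional[str]) -> str:
    if value is None or value == "":
        return "?"
    if re.search(r"\s", value) or value.startswith(("_", "#", "$", "'", '"',
                                                    "[", "]", ";")):
        if "'" not in value:
            return f"'{value}'"
        if '"' not in value:
            return f'"{value}"'
        return f"\n;{value}\n;"
    low = value.lower()
    if low.startswith(("data_", "loop_", "save_", "stop_", "global_")):
        return f"'{value}'"
    return value


def write_mmcif(structure: Structure) -> str:
    """Serialize to PDBx/mmCIF with both label and author identifiers."""
    out: list[str] = []
    block = structure.struct_id or "structure"
    out.append(f"data_{block.replace(' ', '_')}")
    out.append("#")
    if structure.struct_id:
        out.append(f"_entry.id   {_quote(structure.struct_id)}")
        out.append("#")
    if structure.title or structure.struct_id:
        out.append(f"_struct.entry_id   {_quote(structure.struct_id or block)}")
        out.append(f"_struct.title   {_quote(structure.title)}")
        out.append("#")
    if structure.cell is not None:
        c = structure.cell
        out += [f"_cell.length_a   {c.a:.3f}",
                f"_cell.length_b   {c.b:.3f}",
                f"_cell.length_c   {c.c:.3f}",
                f"_cell.angle_alpha   {c.alpha:.2f}",
                f"_cell.angle_beta   {c.beta:.2f}",
                f"_cell.angle_gamma   {c.gamma:.2f}", "#"]
    if structure.space_group_name:
        out.append("_symmetry.space_group_name_H-M   "
                   f"{_quote(structure.space_group_name)}")
        out.append("#")
    if structure.entities:
        out.append("loop_")
        out += ["_entity.id", "_entity.type", "_entity.pdbx_description"]
        for e in structure.entities:
            out.append(f"{e.entity_id} {e.entity_type} "
                       f"{_quote(e.description)}")
        out.append("#")
        poly = [e for e in structure.entities if e.entity_type == "polymer"]
        if poly:
            ptype_names = {"protein": "polypeptide(L)",
                           "dna": "polydeoxyribonucleotide",
                           "rna": "polyribonucleotide"}
            out.append("loop_")
            out += ["_entity_poly.entity_id", "_entity_poly.type",
                    "_entity_poly.pdbx_seq_one_letter_code"]
            for e in poly:
                out.append(f"{e.entity_id} "
                           f"{_quote(ptype_names.get(e.polymer_type, 'other'))} "
                           f"{_quote(e.one_letter_sequence or '?')}")
            out.append("#")
    out.append("loop_")
    out += ["_atom_site.group_PDB", "_atom_site.id",
            "_atom_site.type_symbol", "_atom_site.label_atom_id",
            "_atom_site.label_alt_id", "_atom_site.label_comp_id",
            "_atom_site.label_asym_id", "_atom_site.label_entity_id",
            "_atom_site.label_seq_id", "_atom_site.pdbx_PDB_ins_code",
            "_atom_site.Cartn_x", "_atom_site.Cartn_y", "_atom_site.Cartn_z",
            "_atom_site.occupancy", "_atom_site.B_iso_or_equiv",
            "_atom_site.auth_seq_id", "_atom_site.auth_comp_id",
            "_atom_site.auth_asym_id", "_atom_site.pdbx_PDB_model_num"]
    for mi, model in enumerate(structure.models, start=1):
        for chain in model:
            for gi, g in enumerate(chain.groups, start=1):
                rec = ("ATOM" if chain.is_polymeric
                       and g.category in ("amino_acid", "nucleotide")
                       else "HETATM")
                label_seq = (str(g.seq_id_label)
                             if g.seq_id_label is not None
                             else (str(gi) if chain.is_polymeric else "."))
                for a in g.atoms:
                    x, y, z = a.coords
                    out.append(
                        f"{rec} {a.serial} {a.element or '?'} "
                        f"{_quote(a.name)} {a.alt_loc or '.'} "
                        f"{g.res_name} {chain.asym_id} "
                        f"{chain.entity_id if chain.entity_id else '.'} "
                        f"{label_seq} {g.ins_code or '?'} "
                        f"{x:.3f} {y:.3f} {z:.3f} "
                        f"{a.occupancy:.2f} {a.b_factor:.2f} "
                        f"{g.seq_id_auth} {g.res_name} "
                        f"{chain.auth_id or '.'} {mi}")
    out.append("#")
    return "\n".join(out) + "\n"
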