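"""NeXML reading and writing for annotated character matrices.

NeXML (http://www.nexml.org/2009) lets arbitrary metadata be attached to any
phylogenetic data element.  This module embeds the semantic annotations of a
:class:`~phenomatrix.matrix_model.StudyDocument` using a small, documented
annotation vocabulary bound to the ``pa:`` prefix:

=====================  ========================================================
predicate              meaning
=====================  ========================================================
``pa:taxon``           ResourceMeta on an ``otu``; href is the taxonomy term URI
``pa:phenotype``       ResourceMeta container on a ``state``; one per EQ
                       annotation
``pa:entity``          nested ResourceMeta; href is the entity term URI
``pa:quality``         nested ResourceMeta; href is the quality term URI
``pa:related_entity``  nested ResourceMeta; href is the related-entity term URI
``pa:comment``         nested LiteralMeta; free-text comment
``pa:label``           nested LiteralMeta; cached display label of a term ref
``pa:<key>``           document-level LiteralMeta from ``source_metadata``
=====================  ========================================================

Term references are serialized as full URIs.  OBO-style CURIEs are expanded
through a configurable prefix map whose default maps ``PREFIX:LOCAL`` to
``http://purl.obolibrary.org/obo/PREFIX_LOCAL``; on read, URIs matching that
pattern are contracted back, so CURIE-based documents round-trip exactly.

Output is deterministic: stable element ordering, stable namespace prefixes
and generated ids, so equal documents serialize to byte-identical files.
Unknown document-level metadata read from a file is preserved opaquely in
``source_metadata`` and re-emitted on write.
"""

from __future__ import annotations

import copy
import re
from typing import IO

from lxml import etree

from .errors import NexmlFormatError, NexmlIntegrityError
from .matrix_model import Character, EQAnnotation, State, StudyDocument, Taxon
from .ontology_store import TermRef

NEX_NS = "http://www.nexml.org/2009"
XSI_NS = "http://www.w3.org/2001/XMLSchema-instance"
PA_NS = "http://example.org/phenomatrix/vocab#"

NSMAP = {"nex": NEX_NS, "xsi": XSI_NS, "pa": PA_NS}

_FOREIGN_KEY = "_foreign_meta_"

_OBO_URI = re.compile(r"^http://purl\.obolibrary\.org/obo/([A-Za-z][A-Za-z0-9.]*)_(.+)$")
_CURIE = re.compile(r"^([A-Za-z_][A-Za-z0-9_.-]*):([^:/\s]+)$")
_URI_LIKE = re.compile(r"^[A-Za-z][A-Za-z0-9+.-]*://|^urn:")


class CurieMap:
    """Bidirectional CURIE <-> URI expansion.

    ``overrides`` maps a prefix to a URI base; any other CURIE falls back to
    the OBO library PURL pattern.  Full URIs pass through expansion unchanged
    and are contracted on read when they match a known pattern.
    """

    def __init__(self, overrides: dict[str, str] | None = None):
        self.overrides = dict(overrides or {})

    def expand(self, term_id: str) -> str:
        if _URI_LIKE.match(term_id):
            return term_id
        m = _CURIE.match(term_id)
        if not m:
            return term_id
        prefix, local = m.groups()
        if prefix in self.overrides:
            return self.overrides[prefix] + local
        return f"http://purl.obolibrary.org/obo/{prefix}_{local}"

    def contract(self, uri: str) -> str:
        for prefix, base in sorted(
            self.overrides.items(), key=lambda kv: -len(kv[1])
        ):
            if uri.startswith(base) and len(uri) > len(base):
                return f"{prefix}:{uri[len(base):]}"
        m = _OBO_URI.match(uri)
        if m:
            return f"{m.group(1)}:{m.group(2)}"
        return uri


DEFAULT_CURIE_MAP = CurieMap()


def _nex(tag: str) -> str:
    return f"{{{NEX_NS}}}{tag}"


def _xsi(tag: str) -> str:
    return f"{{{XSI_NS}}}{tag}"


class _IdGen:
    def __init__(self) -> None:
        self.n = 0

    def next(self) -> str:
        self.n += 1
        return f"meta{self.n}"


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _literal_meta(parent, ids: _IdGen, prop: str, content: str) -> None:
    etree.SubElement(
        parent,
        _nex("meta"),
        {
            _xsi("type"): "nex:LiteralMeta",
            "id": ids.next(),
            "property": prop,
            "content": content,
        },
    )


def _resource_meta(parent, ids: _IdGen, rel: str, href: str | None = None):
    attrs = {_xsi("type"): "nex:ResourceMeta", "id": ids.next(), "rel": rel}
    if href is not None:
        attrs["href"] = href
    return etree.SubElement(parent, _nex("meta"), attrs)


def _write_term_ref(parent, ids: _IdGen, rel: str, ref: TermRef, cmap: CurieMap) -> None:
    meta = _resource_meta(parent, ids, rel, cmap.expand(ref.id))
    if ref.cached_label is not None:
        _literal_meta(meta, ids, "pa:label", ref.cached_label)


def build_tree(
    doc: StudyDocument, curie_map: CurieMap | None = None
) -> etree._ElementTree:
    """Build the NeXML element tree for a document (deterministically)."""
    cmap = curie_map or DEFAULT_CURIE_MAP
    ids = _IdGen()
    root = etree.Element(_nex("nexml"), {"version": "0.9"}, nsmap=NSMAP)

    foreign = []
    for key in sorted(doc.source_metadata):
        if key.startswith(_FOREIGN_KEY):
            foreign.append(doc.source_metadata[key])
        else:
            _literal_meta(root, ids, f"pa:{key}", doc.source_metadata[key])
    for raw in foreign:
        root.append(etree.fromstring(raw.encode("utf-8")))

    otus = etree.SubElement(root, _nex("otus"), {"id": "otus1"})
    for i, taxon in enumerate(doc.taxa):
        otu = etree.SubElement(
            otus, _nex("otu"), {"id": f"t{i}", "label": taxon.publication_label}
        )
        if taxon.taxonomy_ref is not None:
            _write_term_ref(otu, ids, "pa:taxon", taxon.taxonomy_ref, cmap)

    if doc.characters:
        chars_el = etree.SubElement(
            root,
            _nex("characters"),
            {
                "id": "chars1",
                "otus": "otus1",
                _xsi("type"): "nex:StandardCells",
            },
        )
        fmt = etree.SubElement(chars_el, _nex("format"))

        # polymorphic symbol sets used per character, in sorted order
        poly_sets: dict[int, list[tuple[str, ...]]] = {}
        for (ti, ci), symbols in doc.cells.items():
            if len(symbols) > 1:
                key = tuple(sorted(symbols))
                poly_sets.setdefault(ci, [])
                if key not in poly_sets[ci]:
                    poly_sets[ci].append(key)
        for ci in poly_sets:
            poly_sets[ci].sort()

        for ci, char in enumerate(doc.characters):
            states_el = etree.SubElement(fmt, _nex("states"), {"id": f"states{ci}"})
            for state in char.states:
                st = etree.SubElement(
                    states_el,
                    _nex("state"),
                    {
                        "id": f"s{ci}_{state.symbol}",
                        "symbol": state.symbol,
                        "label": state.label,
                    },
                )
                for ann in state.annotations:
                    container = _resource_meta(st, ids, "pa:phenotype")
                    if ann.entity is not None:
                        _write_term_ref(container, ids, "pa:entity", ann.entity, cmap)
                    if ann.quality is not None:
                        _write_term_ref(container, ids, "pa:quality", ann.quality, cmap)
                    if ann.related_entity is not None:
                        _write_term_ref(
                            container, ids, "pa:related_entity", ann.related_entity, cmap
                        )
                    if ann.comment is not None:
                        _literal_meta(container, ids, "pa:comment", ann.comment)
            for k, key in enumerate(poly_sets.get(ci, [])):
                poly = etree.SubElement(
                    states_el,
                    _nex("polymorphic_state_set"),
                    {
                        "id": f"p{ci}_{k}",
                        "symbol": str(len(char.states) + k),
                    },
                )
                for sym in key:
                    etree.SubElement(poly, _nex("member"), {"state": f"s{ci}_{sym}"})
        for ci, char in enumerate(doc.characters):
            etree.SubElement(
                fmt,
                _nex("char"),
                {"id": f"c{ci}", "states": f"states{ci}", "label": char.label},
            )

        matrix = etree.SubElement(chars_el, _nex("matrix"))
        for ti in range(len(doc.taxa)):
            row = etree.SubElement(matrix, _nex("row"), {"id": f"r{ti}", "otu": f"t{ti}"})
            for ci in range(len(doc.characters)):
                symbols = doc.cells.get((ti, ci))
                if symbols is None:
                    continue
                if len(symbols) == 1:
                    state_id = f"s{ci}_{next(iter(symbols))}"
                else:
                    key = tuple(sorted(symbols))
                    state_id = f"p{ci}_{poly_sets[ci].index(key)}"
                etree.SubElement(
                    row, _nex("cell"), {"char": f"c{ci}", "state": state_id}
                )

    return etree.ElementTree(root)


def nexml_bytes(doc: StudyDocument, curie_map: CurieMap | None = None) -> bytes:
    """Serialize a document to NeXML bytes (byte-deterministic)."""
    tree = build_tree(doc, curie_map)
    return etree.tostring(
        tree, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def write_nexml(
    doc: StudyDocument,
    destination: str | IO[bytes],
    curie_map: CurieMap | None = None,
) -> None:
    """Write a document as NeXML to a path or binary file object."""
    data = nexml_bytes(doc, curie_map)
    if hasattr(destination, "write"):
        destination.write(data)
    else:
        with open(destination, "wb") as fh:
            fh.write(data)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _meta_predicate(meta) -> tuple[str | None, str | None]:
    """Resolve the meta's predicate CURIE against the element's nsmap.

    Returns (namespace URI, local name); (None, None) when unresolvable.
    """
    pred = meta.get("rel") or meta.get("property")
    if pred is None:
        return None, None
    prefix, _, local = pred.rpartition(":")
    ns = meta.nsmap.get(prefix or None)
    return ns, local


def _normalize_foreign(elem) -> str:
    """Serialize a foreign element as it will appear inside our output tree.

    Adopting the element into a scratch root carrying the writer's namespace
    map makes lxml reconcile prefixes exactly as :func:`write_nexml` will, so
    the stored opaque string is identical across read/write cycles.
    """
    scratch = etree.Element(_nex("nexml"), nsmap=NSMAP)
    scratch.append(copy.deepcopy(elem))
    child = scratch[0]
    child.tail = None
    return etree.tostring(child, encoding="unicode").strip()


def _read_term_ref(meta, cmap: CurieMap) -> TermRef:
    href = meta.get("href")
    if href is None:
        raise NexmlFormatError("term-reference meta is missing its href")
    label = None
    for child in meta.findall(_nex("meta")):
        ns, local = _meta_predicate(child)
        if ns == PA_NS and local == "label":
            label = child.get("content")
    return TermRef(id=cmap.contract(href), cached_label=label)


def _read_annotation(container, cmap: CurieMap) -> EQAnnotation:
    entity = quality = related = None
    comment = None
    for child in container.findall(_nex("meta")):
        ns, local = _meta_predicate(child)
        if ns != PA_NS:
            continue
        if local == "entity":
            entity = _read_term_ref(child, cmap)
        elif local == "quality":
            quality = _read_term_ref(child, cmap)
        elif local == "related_entity":
            related = _read_term_ref(child, cmap)
        elif local == "comment":
            comment = child.get("content")
    return EQAnnotation(
        entity=entity, quality=quality, related_entity=related, comment=comment
    )


def read_nexml(source: str | IO[bytes]) -> StudyDocument:
    """Parse a NeXML file back into a :class:`StudyDocument`.

    Unknown document-level metadata elements are preserved opaquely in
    ``source_metadata`` (keys ``_foreign_meta_<n>``) and re-emitted by
    :func:`write_nexml`.
    """
    parser = etree.XMLParser(remove_blank_text=True)
    try:
        tree = etree.parse(source, parser)
    except etree.XMLSyntaxError as exc:
        raise NexmlFormatError(f"not well-formed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != _nex("nexml"):
        raise NexmlFormatError(f"root element is {root.tag}, expected NeXML")
    cmap = DEFAULT_CURIE_MAP

    doc = StudyDocument()

    foreign_n = 0
    for child in root:
        if child.tag in (_nex("otus"), _nex("characters"), _nex("trees")):
            continue
        if child.tag == _nex("meta"):
            ns, local = _meta_predicate(child)
            if ns == PA_NS and local is not None:
                doc.source_metadata[local] = child.get("content", "")
                continue
        if isinstance(child.tag, str):  # skip comments/PIs
            doc.source_metadata[f"{_FOREIGN_KEY}{foreign_n}"] = _normalize_foreign(child)
            foreign_n += 1

    otus = root.find(_nex("otus"))
    otu_index: dict[str, int] = {}
    if otus is not None:
        for i, otu in enumerate(otus.findall(_nex("otu"))):
            taxonomy_ref = None
            for meta in otu.findall(_nex("meta")):
                ns, local = _meta_predicate(meta)
                if ns == PA_NS and local == "taxon":
                    taxonomy_ref = _read_term_ref(meta, cmap)
            doc.taxa.append(
                Taxon(
                    publication_label=otu.get("label", otu.get("id", f"taxon {i}")),
                    taxonomy_ref=taxonomy_ref,
                )
            )
            otu_index[otu.get("id", "")] = i

    chars_el = root.find(_nex("characters"))
    if chars_el is None:
        return doc

    fmt = chars_el.find(_nex("format"))
    if fmt is None:
        raise NexmlFormatError("characters block has no format element")

    # states-block id -> (state-id -> symbol, state-id -> set of symbols)
    states_blocks: dict[str, dict[str, State]] = {}
    state_symbols: dict[str, dict[str, frozenset[str]]] = {}
    for states_el in fmt.findall(_nex("states")):
        sid = states_el.get("id", "")
        block: dict[str, State] = {}
        symbol_of: dict[str, str] = {}
        for st in states_el.findall(_nex("state")):
            symbol = st.get("symbol")
            if symbol is None:
                raise NexmlFormatError(f"state {st.get('id')!r} has no symbol")
            annotations = []
            for meta in st.findall(_nex("meta")):
                ns, local = _meta_predicate(meta)
                if ns == PA_NS and local == "phenotype":
                    annotations.append(_read_annotation(meta, cmap))
            block[st.get("id", "")] = State(
                symbol=symbol, label=st.get("label", ""), annotations=annotations
            )
            symbol_of[st.get("id", "")] = symbol
        sets: dict[str, frozenset[str]] = {
            stid: frozenset({sym}) for stid, sym in symbol_of.items()
        }
        for poly in states_el.findall(_nex("polymorphic_state_set")):
            members = set()
            for member in poly.findall(_nex("member")):
                ref = member.get("state")
                if ref not in symbol_of:
                    raise NexmlIntegrityError(
                        f"polymorphic set {poly.get('id')!r} references "
                        f"undeclared state {ref!r}"
                    )
                members.add(symbol_of[ref])
            sets[poly.get("id", "")] = frozenset(members)
        states_blocks[sid] = block
        state_symbols[sid] = sets

    char_index: dict[str, int] = {}
    char_states: dict[str, str] = {}
    for ci, char_el in enumerate(fmt.findall(_nex("char"))):
        states_ref = char_el.get("states", "")
        if states_ref not in states_blocks:
            raise NexmlIntegrityError(
                f"char {char_el.get('id')!r} references undeclared states block "
                f"{states_ref!r}"
            )
        cid = char_el.get("id", "")
        char_index[cid] = ci
        char_states[cid] = states_ref
        doc.characters.append(
            Character(
                label=char_el.get("label", ""),
                states=[copy.deepcopy(s) for s in states_blocks[states_ref].values()],
            )
        )

    matrix = chars_el.find(_nex("matrix"))
    if matrix is not None:
        for row in matrix.findall(_nex("row")):
            otu_ref = row.get("otu", "")
            if otu_ref not in otu_index:
                raise NexmlIntegrityError(
                    f"row {row.get('id')!r} references undeclared otu {otu_ref!r}"
                )
            ti = otu_index[otu_ref]
            for cell in row.findall(_nex("cell")):
                cref = cell.get("char", "")
                if cref not in char_index:
                    raise NexmlIntegrityError(
                        f"row {row.get('id')!r} has a cell for undeclared char {cref!r}"
                    )
                sref = cell.get("state", "")
                sets = state_symbols[char_states[cref]]
                if sref not in sets:
                    raise NexmlIntegrityError(
                        f"row {row.get('id')!r}, char {cref!r}: cell references "
                        f"undeclared state {sref!r}"
                    )
                doc.cells[(ti, char_index[cref])] = sets[sref]
    return doc


# ---------------------------------------------------------------------------
# Structural validation
# ---------------------------------------------------------------------------

def validate_nexml(source: str | IO[bytes]) -> list[str]:
    """Structural validation of a NeXML file.

    Checks the constraints the NeXML schema imposes that matter for this
    tool: root element and version, id uniqueness, and referential integrity
    of otus/char/state references.  Returns a list of problems (empty when
    the file is structurally valid).
    """
    problems: list[str] = []
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        return [f"not well-formed XML: {exc}"]
    root = tree.getroot()
    if root.tag != _nex("nexml"):
        return [f"root element is {root.tag}, expected {{{NEX_NS}}}nexml"]
    if root.get("version") != "0.9":
        problems.append(f"unsupported NeXML version {root.get('version')!r}")

    seen_ids: set[str] = set()
    for el in root.iter():
        if not isinstance(el.tag, str) or not el.tag.startswith(f"{{{NEX_NS}}}"):
            continue
        el_id = el.get("id")
        if el_id is not None:
            if el_id in seen_ids:
                problems.append(f"duplicate id {el_id!r}")
            seen_ids.add(el_id)

    otus_ids = {el.get("id") for el in root.findall(_nex("otus"))}
    otu_ids = {
        otu.get("id")
        for otus in root.findall(_nex("otus"))
        for otu in otus.findall(_nex("otu"))
    }
    for chars_el in root.findall(_nex("characters")):
        if chars_el.get("otus") not in otus_ids:
            problems.append(
                f"characters {chars_el.get('id')!r} references unknown otus block"
            )
        fmt = chars_el.find(_nex("format"))
        if fmt is None:
            problems.append(f"characters {chars_el.get('id')!r} has no format")
            continue
        state_ids: dict[str, set[str]] = {}
        for states_el in fmt.findall(_nex("states")):
            ids_here = set()
            for st in states_el.findall(_nex("state")):
                ids_here.add(st.get("id"))
            for poly in states_el.findall(_nex("polymorphic_state_set")):
                for member in poly.findall(_nex("member")):
                    if member.get("state") not in ids_here:
                        problems.append(
                            f"polymorphic set {poly.get('id')!r} member references "
                            f"unknown state {member.get('state')!r}"
                        )
                ids_here.add(poly.get("id"))
            state_ids[states_el.get("id", "")] = ids_here
        char_to_states: dict[str, str] = {}
        for char_el in fmt.findall(_nex("char")):
            sref = char_el.get("states", "")
            if sref not in state_ids:
                problems.append(
                    f"char {char_el.get('id')!r} references unknown states {sref!r}"
                )
            char_to_states[char_el.get("id", "")] = sref
        matrix = chars_el.find(_nex("matrix"))
        if matrix is None:
            continue
        for row in matrix.findall(_nex("row")):
            if row.get("otu") not in otu_ids:
                problems.append(
                    f"row {row.get('id')!r} references unknown otu {row.get('otu')!r}"
                )
            for cell in row.findall(_nex("cell")):
                cref = cell.get("char", "")
                if cref not in char_to_states:
                    problems.append(
                        f"cell in row {row.get('id')!r} references unknown char {cref!r}"
                    )
                    continue
                valid_states = state_ids.get(char_to_states[cref], set())
                if cell.get("state") not in valid_states:
                    problems.append(
                        f"cell in row {row.get('id')!r} references unknown state "
                        f"{cell.get('state')!r}"
                    )
    return problems
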