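"""Readers and writers for the linked MATSim household/person containers.

Populations are published as a pair of XML files: a households file
(households_v1.0 structure: per household a ``<members>`` list of
``personId`` references, an ``<income>`` element carrying the upper value
of the income band in 2011 ZAR, and an ``<attributes>`` list), and a
population file (population_v6 structure: per person an ``<attributes>``
list including a ``householdId`` back-pointer).  Every attribute is
written with its name and the Java class-type label the dialect uses
(plain strings, ``java.lang.Integer`` for counts and ids, and the MATSim
coordinate class for the WGS84 home coordinate).

Writers are byte-deterministic for a fixed population; ``.gz`` sinks are
gzip-wrapped (readers sniff the magic bytes).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .assembly import SyntheticPopulation

HOUSEHOLDS_NS = "http://www.matsim.org/files/dtd"
HOUSEHOLDS_SCHEMA = "http://www.matsim.org/files/dtd/households_v1.0.xsd"
POPULATION_DTD = "http://www.matsim.org/files/dtd/population_v6.dtd"
XSI = "http://www.w3.org/2001/XMLSchema-instance"

JAVA_STRING = "java.lang.String"
JAVA_INTEGER = "java.lang.Integer"
JAVA_DOUBLE = "java.lang.Double"
MATSIM_COORD = "org.matsim.api.core.v01.Coord"

Attribute = tuple[str, str, str]  # (name, java class label, value)


@dataclass
class HouseholdEntry:
    id: str
    members: list[str]
    income_value: float | None  # upper value of the income band, 2011 ZAR
    income_currency: str = "ZAR"
    attributes: list[Attribute] = field(default_factory=list)


@dataclass
class HouseholdsDocument:
    households: list[HouseholdEntry] = field(default_factory=list)

    def validate(self) -> None:
        seen = set()
        for h in self.households:
            if h.id in seen:
                raise ValueError(f"duplicate household id {h.id!r}")
            seen.add(h.id)
            if not h.members:
                raise ValueError(f"household {h.id!r} has an empty member list")

    def member_ids(self) -> set[str]:
        return {m for h in self.households for m in h.members}


@dataclass
class PersonEntry:
    id: str
    attributes: list[Attribute] = field(default_factory=list)

    def attribute(self, name: str) -> str | None:
        for n, _, v in self.attributes:
            if n == name:
                return v
        return None


@dataclass
class PopulationDocument:
    persons: list[PersonEntry] = field(default_factory=list)

    def validate(self) -> None:
        seen = set()
        for p in self.persons:
            if p.id in seen:
                raise ValueError(f"duplicate person id {p.id!r}")
            seen.add(p.id)


# ---------------------------------------------------------------------------
# Document construction from a SyntheticPopulation
# ---------------------------------------------------------------------------


def _fmt_coord(lon: float, lat: float) -> str:
    return f"({lon:.6f};{lat:.6f})"


def households_document(pop: SyntheticPopulation) -> HouseholdsDocument:
    members_of: dict[int, list[str]] = {}
    for pid, hid in zip(pop.persons["pid"], pop.persons["hid"]):
        members_of.setdefault(int(hid), []).append(str(int(pid)))
    doc = HouseholdsDocument()
    for _, row in pop.households.iterrows():
        attrs: list[Attribute] = [
            ("housingType", JAVA_STRING, str(row["housing"])),
            ("mainDwellingType", JAVA_STRING, str(row["dwelling"])),
            ("rooms", JAVA_INTEGER, str(int(row["rooms"]))),
            ("tenure", JAVA_STRING, str(row["tenure"])),
        ]
        value = row["income_value"]
        has_value = value is not None and value == value  # NaN check
        if not has_value:
            attrs.append(("income", JAVA_STRING, str(row["income"])))
        attrs.append(
            ("homeCoordWGS", MATSIM_COORD, _fmt_coord(row["lon"], row["lat"]))
        )
        doc.households.append(
            HouseholdEntry(
                id=str(int(row["hid"])),
                members=members_of.get(int(row["hid"]), []),
                income_value=float(value) if has_value else None,
                attributes=attrs,
            )
        )
    doc.validate()
    return doc


def population_document(pop: SyntheticPopulation) -> PopulationDocument:
    doc = PopulationDocument()
    for _, row in pop.persons.iterrows():
        doc.persons.append(
            PersonEntry(
                id=str(int(row["pid"])),
                attributes=[
                    ("age", JAVA_STRING, str(row["age"])),
                    ("gender", JAVA_STRING, str(row["gender"])),
                    ("race", JAVA_STRING, str(row["race"])),
                    ("employment", JAVA_STRING, str(row["employ"])),
                    ("education", JAVA_STRING, str(row["edu"])),
                    ("school", JAVA_STRING, str(row["study"])),
                    ("householdId", JAVA_INTEGER, str(int(row["hid"]))),
                ],
            )
        )
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _attributes_element(parent, attrs: list[Attribute], ns: str = "") -> None:
    if not attrs:
        return
    el = etree.SubElement(parent, f"{ns}attributes")
    for name, clazz, value in attrs:
        a = etree.SubElement(el, f"{ns}attribute", name=name)
        a.set("class", clazz)
        a.text = value


def _serialize_households(doc: HouseholdsDocument) -> bytes:
    ns = f"{{{HOUSEHOLDS_NS}}}"
    nsmap = {None: HOUSEHOLDS_NS, "xsi": XSI}
    root = etree.Element(f"{ns}households", nsmap=nsmap)
    root.set(f"{{{XSI}}}schemaLocation", f"{HOUSEHOLDS_NS} {HOUSEHOLDS_SCHEMA}")
    for h in doc.households:
        hh = etree.SubElement(root, f"{ns}household", id=h.id)
        members = etree.SubElement(hh, f"{ns}members")
        for pid in h.members:
            etree.SubElement(members, f"{ns}personId", refId=pid)
        if h.income_value is not None:
            inc = etree.SubElement(hh, f"{ns}income", currency=h.income_currency)
            inc.set("period", "year")
            inc.text = f"{h.income_value:.0f}"
        _attributes_element(hh, h.attributes, ns)
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def _serialize_population(doc: PopulationDocument) -> bytes:
    root = etree.Element("population")
    for p in doc.persons:
        person = etree.SubElement(root, "person", id=p.id)
        _attributes_element(person, p.attributes)
    return etree.tostring(
        root,
        xml_declaration=True,
        encoding="UTF-8",
        pretty_print=True,
        doctype=f'<!DOCTYPE population SYSTEM "{POPULATION_DTD}">',
    )


def _write_bytes(payload: bytes, sink, compress: bool | None) -> None:
    if isinstance(sink, (str, Path)):
        path = Path(sink)
        if compress is None:
            compress = path.suffix == ".gz"
        data = _gzip_bytes(payload) if compress else payload
        path.write_bytes(data)
    else:
        data = _gzip_bytes(payload) if compress else payload
        sink.write(data)


def _gzip_bytes(payload: bytes) -> bytes:
    buf = io.BytesIO()
    # fixed mtime and empty filename keep the output byte-deterministic
    with gzip.GzipFile(fileobj=buf, mode="wb", mtime=0, filename="") as fh:
        fh.write(payload)
    return buf.getvalue()


def _read_bytes(source) -> bytes:
    if isinstance(source, (str, Path)):
        data = Path(source).read_bytes()
    elif isinstance(source, bytes):
        data = source
    else:
        data = source.read()
    if data[:2] == b"\x1f\x8b":
        data = gzip.decompress(data)
    return data


def write_households_doc(doc: HouseholdsDocument, sink, compress: bool | None = None) -> None:
    doc.validate()
    _write_bytes(_serialize_households(doc), sink, compress)


def write_population_doc(doc: PopulationDocument, sink, compress: bool | None = None) -> None:
    doc.validate()
    _write_bytes(_serialize_population(doc), sink, compress)


def write_households(pop: SyntheticPopulation, sink, compress: bool | None = None) -> None:
    """Write the households container for a population."""
    write_households_doc(households_document(pop), sink, compress)


def write_population(pop: SyntheticPopulation, sink, compress: bool | None = None) -> None:
    """Write the persons container for a population."""
    write_population_doc(population_document(pop), sink, compress)


def _parse(data: bytes):
    try:
        return etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed XML: {exc}") from exc


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _read_attributes(el) -> list[Attribute]:
    out: list[Attribute] = []
    for child in el:
        if _local(child.tag) == "attributes":
            for a in child:
                if _local(a.tag) == "attribute":
                    out.append((a.get("name"), a.get("class"), a.text or ""))
    return out


def read_households(source) -> HouseholdsDocument:
    root = _parse(_read_bytes(source))
    doc = HouseholdsDocument()
    for hh in root:
        if _local(hh.tag) != "household":
            continue
        members: list[str] = []
        income_value = None
        currency = "ZAR"
        for child in hh:
            tag = _local(child.tag)
            if tag == "members":
                members = [m.get("refId") for m in child if _local(m.tag) == "personId"]
            elif tag == "income":
                income_value = float(child.text)
                currency = child.get("currency", currency)
        doc.households.append(
            HouseholdEntry(
                id=hh.get("id"),
                members=members,
                income_value=income_value,
                income_currency=currency,
                attributes=_read_attributes(hh),
            )
        )
    doc.validate()
    return doc


def read_population(source) -> PopulationDocument:
    root = _parse(_read_bytes(source))
    doc = PopulationDocument()
    for el in root:
        if _local(el.tag) != "person":
            continue
        doc.persons.append(PersonEntry(id=el.get("id"), attributes=_read_attributes(el)))
    doc.validate()
    return doc


@dataclass
class LinkReport:
    """Consistency report for a households/population file pair."""

    dangling_members: list[str] = field(default_factory=list)
    orphan_persons: list[str] = field(default_factory=list)
    backpointer_mismatches: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.dangling_members or self.orphan_persons or self.backpointer_mismatches
        )


def link_check(h: HouseholdsDocument, p: PopulationDocument) -> LinkReport:
    """Cross-check member references and household back-pointers."""
    report = LinkReport()
    person_ids = {pe.id for pe in p.persons}
    household_of: dict[str, str] = {}
    for hh in h.households:
        for m in hh.members:
            household_of[m] = hh.id
            if m not in person_ids:
                report.dangling_members.append(m)
    for pe in p.persons:
        back = pe.attribute("householdId")
        if pe.id not in household_of:
            report.orphan_persons.append(pe.id)
        elif back is not None and back != household_of[pe.id]:
            report.backpointer_mismatches.append(pe.id)
    return report
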