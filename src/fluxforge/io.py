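"""Model import/export: SBML, Metatool text, and flat TSV bundles.

SBML export targets Level 3 + the fbc package (flux bounds, gene-product
associations, the active objective marking the biomass reaction); import
additionally accepts Level 2 files with kinetic-law bound parameters and
note-based "GENE_ASSOCIATION:" strings.

The Metatool dialect is the classic sectioned text format (-ENZREV,
-ENZIRREV, -METINT, -METEXT, -CAT).  It carries no numeric bounds, so
reversible reactions get symmetric default bounds and irreversible ones
[0, M]; biomass designation and GPRs are not representable.

The flat bundle is tab-separated with a header row: a metabolite list, a
reaction list, a dense stoichiometric matrix (metabolite ids in the first
column, reaction ids across the header) and an optional gene-rules table.

All paths may be gzip-compressed (``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import io as _io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import libsbml
import pandas as pd

from . import config
from .gpr import GeneRule, rule_or_none
from .model import MetabolicModel, Metabolite, ModelError, Reaction

logger = logging.getLogger(__name__)


class FormatError(ModelError):
    """Malformed or unsupported input file."""


def _read_text(path) -> str:
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            return fh.read()
    return path.read_text()


def _write_text(path, text: str) -> None:
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        path.write_text(text)


# ---------------------------------------------------------------------------
# flat TSV bundle


@dataclass(frozen=True)
class FlatFileBundle:
    reactions_path: Path
    metabolites_path: Path
    matrix_path: Path
    gene_rules_path: Optional[Path] = None

    @classmethod
    def in_dir(cls, directory) -> "FlatFileBundle":
        d = Path(directory)
        rules = d / "gene_rules.tsv"
        return cls(
            reactions_path=d / "reactions.tsv",
            metabolites_path=d / "metabolites.tsv",
            matrix_path=d / "matrix.tsv",
            gene_rules_path=rules if rules.exists() else None,
        )


def read_flat(bundle: FlatFileBundle) -> MetabolicModel:
    """Assemble a model from a flat TSV bundle."""
    mets_df = pd.read_csv(bundle.metabolites_path, sep="\t", dtype=str)
    rxns_df = pd.read_csv(bundle.reactions_path, sep="\t", dtype=str)
    mat_df = pd.read_csv(bundle.matrix_path, sep="\t", index_col=0)

    for df, what, path in ((mets_df, "metabolite", bundle.metabolites_path),
                           (rxns_df, "reaction", bundle.reactions_path)):
        dup = df["id"][df["id"].duplicated()]
        if not dup.empty:
            raise FormatError(f"duplicate {what} ids {sorted(set(dup))} in {path}")

    n_m, n_r = len(mets_df), len(rxns_df)
    if mat_df.shape != (n_m, n_r):
        raise FormatError(
            f"matrix in {bundle.matrix_path} is {mat_df.shape[0]}x{mat_df.shape[1]}, "
            f"expected {n_m} metabolites x {n_r} reactions"
        )

    metabolites = [
        Metabolite(
            id=row["id"],
            name=row.get("name", "") if isinstance(row.get("name"), str) else "",
            compartment=row["compartment"] if isinstance(row.get("compartment"), str) and row["compartment"] else None,
            external=str(row.get("external", "0")) in ("1", "true", "True"),
        )
        for _, row in mets_df.iterrows()
    ]

    rules: Dict[str, GeneRule] = {}
    genes: Set[str] = set()
    if bundle.gene_rules_path is not None:
        rdf = pd.read_csv(bundle.gene_rules_path, sep="\t", dtype=str)
        for _, row in rdf.iterrows():
            rule = rule_or_none(row["rule"])
            if rule is not None:
                rules[row["reaction_id"]] = rule
                genes |= rule.genes

    reactions = []
    biomass = None
    for _, row in rxns_df.iterrows():
        rid = row["id"]
        if rid not in mat_df.columns:
            raise FormatError(f"reaction {rid!r} missing from matrix columns")
        col = mat_df[rid]
        stoich = {mid: float(v) for mid, v in col.items() if float(v) != 0.0}
        if not stoich:
            raise FormatError(f"reaction {rid!r} has an all-zero matrix column")
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=float(row["lower_bound"]),
                upper_bound=float(row["upper_bound"]),
                name=row.get("name", "") if isinstance(row.get("name"), str) else "",
                gene_rule=rules.get(rid),
            )
        )
        if str(row.get("biomass", "0")) in ("1", "true", "True"):
            biomass = rid

    met_ids = {m.id for m in metabolites}
    orphans = [mid for mid in mat_df.index if (mat_df.loc[mid] == 0).all()]
    for mid in orphans:
        logger.warning("metabolite %r participates in no reaction (orphan row)", mid)
    unknown_rows = set(mat_df.index) - met_ids
    if unknown_rows:
        raise FormatError(f"matrix rows {sorted(unknown_rows)} not in metabolite list")

    return MetabolicModel(
        metabolites=metabolites, reactions=reactions, biomass_reaction=biomass,
        genes=genes, name=str(Path(bundle.matrix_path).parent.name),
    )


def _write_flat(model: MetabolicModel, directory) -> List[Path]:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    mets = pd.DataFrame(
        [
            {
                "id": m.id, "name": m.name, "compartment": m.compartment or "",
                "external": int(m.external),
            }
            for m in model.metabolites.values()
        ]
    )
    rxns = pd.DataFrame(
        [
            {
                "id": r.id, "name": r.name,
                "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
                "biomass": int(r.id == model.biomass_reaction),
            }
            for r in model.reactions.values()
        ]
    )
    mat = pd.DataFrame(
        0.0, index=list(model.metabolites), columns=list(model.reactions)
    )
    for r in model.reactions.values():
        for mid, c in r.stoichiometry.items():
            mat.loc[mid, r.id] = float(c)
    paths = [d / "metabolites.tsv", d / "reactions.tsv", d / "matrix.tsv"]
    mets.to_csv(paths[0], sep="\t", index=False)
    rxns.to_csv(paths[1], sep="\t", index=False)
    mat.to_csv(paths[2], sep="\t", index_label="metabolite")
    rules = [
        {"reaction_id": r.id, "rule": r.gene_rule.expression}
        for r in model.reactions.values()
        if r.gene_rule is not None
    ]
    if rules:
        p = d / "gene_rules.tsv"
        pd.DataFrame(rules).to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Metatool


_METATOOL_SECTIONS = ("-ENZREV", "-ENZIRREV", "-METINT", "-METEXT", "-CAT")


def read_metatool(path) -> MetabolicModel:
    """Parse the classic Metatool sectioned text format."""
    text = _read_text(path)
    sections: Dict[str, List[str]] = {}
    current = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.split()[0] in _METATOOL_SECTIONS:
            current = line.split()[0]
            sections[current] = []
            rest = line[len(current):].strip()
            if rest:
                sections[current].append(rest)
            continue
        if current is not None:
            sections[current].append(line)
    missing = [s for s in _METATOOL_SECTIONS if s not in sections]
    if missing:
        raise FormatError(f"Metatool file {path} missing section(s) {missing}")

    rev = set(" ".join(sections["-ENZREV"]).split())
    irrev = set(" ".join(sections["-ENZIRREV"]).split())
    internal = " ".join(sections["-METINT"]).split()
    external = " ".join(sections["-METEXT"]).split()
    declared = rev | irrev

    M = config.DEFAULT_BOUND
    metabolites = [Metabolite(id=m, name=m) for m in internal] + [
        Metabolite(id=m, name=m, external=True) for m in external
    ]
    known_mets = {m.id for m in metabolites}

    reactions = []
    seen = set()
    for line in sections["-CAT"]:
        if ":" not in line or "=" not in line:
            raise FormatError(f"malformed -CAT line: {line!r}")
        rid, eqn = line.split(":", 1)
        rid = rid.strip()
        if rid not in declared:
            raise FormatError(
                f"reaction {rid!r} appears in -CAT but is not declared in "
                "-ENZREV or -ENZIRREV"
            )
        seen.add(rid)
        lhs, rhs = eqn.split("=", 1)
        rhs = rhs.strip().rstrip(".").strip()
        stoich: Dict[str, float] = {}
        for side, sign in ((lhs, -1.0), (rhs, 1.0)):
            for term in side.split("+"):
                term = term.strip().rstrip(".").strip()
                if not term:
                    continue
                parts = term.split()
                if len(parts) == 2:
                    coef, mid = float(parts[0]), parts[1]
                elif len(parts) == 1:
                    coef, mid = 1.0, parts[0]
                else:
                    raise FormatError(f"cannot parse term {term!r} in {line!r}")
                if mid not in known_mets:
                    raise FormatError(f"-CAT line for {rid!r} uses undeclared metabolite {mid!r}")
                stoich[mid] = stoich.get(mid, 0.0) + sign * coef
        stoich = {m: c for m, c in stoich.items() if c != 0.0}
        lb = -M if rid in rev else 0.0
        reactions.append(Reaction(id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=M, name=rid))
    undeclared = declared - seen
    if undeclared:
        raise FormatError(f"reactions {sorted(undeclared)} declared but absent from -CAT")
    return MetabolicModel(
        metabolites=metabolites, reactions=reactions, name=str(Path(path).stem)
    )


def _format_metatool(model: MetabolicModel) -> str:
    rev = [r.id for r in model.reactions.values() if r.reversible]
    irrev = [r.id for r in model.reactions.values() if not r.reversible]

    def eqn(r: Reaction) -> str:
        def side(sign):
            terms = []
            for mid, c in r.stoichiometry.items():
                v = sign * float(c)
                if v > 0:
                    terms.append(f"{v:g} {mid}" if v != 1 else mid)
            return " + ".join(terms)

        return f"{r.id} : {side(-1)} = {side(1)} ."

    lines = ["-ENZREV", " ".join(rev), "", "-ENZIRREV", " ".join(irrev), "",
             "-METINT", " ".join(model.internal_metabolite_ids), "",
             "-METEXT", " ".join(model.external_metabolite_ids), "", "-CAT"]
    lines += [eqn(r) for r in model.reactions.values()]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# SBML


def read_sbml(path) -> MetabolicModel:
    """Read SBML Level 2 or 3, with fbc bounds/GPRs when present."""
    doc = libsbml.readSBMLFromString(_read_text(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(
            f"SBML parse error in {path} at line {err.getLine()}: {err.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError(f"{path} contains no SBML model")
    fbc = sbml_model.getPlugin("fbc")

    metabolites = []
    for sp in sbml_model.getListOfSpecies():
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or None,
                external=bool(sp.getBoundaryCondition()),
            )
        )

    genes: Set[str] = set()
    gp_label: Dict[str, str] = {}
    if fbc is not None:
        for gp in fbc.getListOfGeneProducts():
            label = gp.getLabel() or gp.getId()
            gp_label[gp.getId()] = label
            genes.add(label)

    M = config.DEFAULT_BOUND
    reactions = []
    biomass = None
    for rx in sbml_model.getListOfReactions():
        stoich: Dict[str, float] = {}
        for sr in rx.getListOfReactants():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for sr in rx.getListOfProducts():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        lb = -M if rx.getReversible() else 0.0
        ub = M
        rfbc = rx.getPlugin("fbc")
        if rfbc is not None and rfbc.isSetLowerFluxBound():
            lb = sbml_model.getParameter(rfbc.getLowerFluxBound()).getValue()
            ub = sbml_model.getParameter(rfbc.getUpperFluxBound()).getValue()
        elif rx.isSetKineticLaw():
            kl = rx.getKineticLaw()
            plb = kl.getParameter("LOWER_BOUND")
            pub = kl.getParameter("UPPER_BOUND")
            if plb is not None:
                lb = plb.getValue()
            if pub is not None:
                ub = pub.getValue()

        rule = None
        if rfbc is not None and rfbc.isSetGeneProductAssociation():
            infix = rfbc.getGeneProductAssociation().getAssociation().toInfix()
            for gpid, label in gp_label.items():
                infix = re.sub(rf"\b{re.escape(gpid)}\b", label, infix)
            rule = rule_or_none(infix)
        elif rx.isSetNotes():
            notes = rx.getNotesString()
            mobj = re.search(r"GENE_ASSOCIATION:\s*([^<\n]+)", notes)
            if mobj:
                rule = rule_or_none(mobj.group(1).strip())
        if rule is not None:
            genes |= rule.genes

        reactions.append(
            Reaction(
                id=rx.getId(), stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                name=rx.getName() or "", gene_rule=rule,
            )
        )

    if fbc is not None and fbc.getNumObjectives() > 0:
        active = fbc.getActiveObjective() or fbc.getObjective(0)
        if active is not None and active.getNumFluxObjectives() > 0:
            biomass = active.getFluxObjective(0).getReaction()

    return MetabolicModel(
        metabolites=metabolites, reactions=reactions, biomass_reaction=biomass,
        genes=genes, name=sbml_model.getId() or str(Path(path).stem),
    )


def _check_call(rc, what: str):
    if rc not in (libsbml.LIBSBML_OPERATION_SUCCESS, None):
        raise FormatError(f"libsbml error while setting {what}: code {rc}")


def _format_sbml(model: MetabolicModel) -> str:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(re.sub(r"[^A-Za-z0-9_]", "_", model.name) or "model")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = {m.compartment or ("e" if m.external else "c") for m in model.metabolites.values()}
    for cid in sorted(compartments):
        comp = sm.createCompartment()
        _check_call(comp.setId(cid), f"compartment {cid}")
        comp.setConstant(True)
        comp.setSize(1.0)

    for m in model.metabolites.values():
        sp = sm.createSpecies()
        rc = sp.setId(m.id)
        if rc != libsbml.LIBSBML_OPERATION_SUCCESS:
            raise FormatError(f"metabolite id {m.id!r} is not a valid SBML identifier")
        sp.setName(m.name)
        sp.setCompartment(m.compartment or ("e" if m.external else "c"))
        sp.setBoundaryCondition(m.external)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)

    bound_params: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for g in sorted(model.genes):
        gp = mplug.createGeneProduct()
        rc = gp.setId(re.sub(r"[^A-Za-z0-9_]", "_", f"G_{g}"))
        _check_call(rc, f"gene {g}")
        gp.setLabel(g)

    label_to_id = {g: re.sub(r"[^A-Za-z0-9_]", "_", f"G_{g}") for g in model.genes}

    for r in model.reactions.values():
        rx = sm.createReaction()
        rc = rx.setId(r.id)
        if rc != libsbml.LIBSBML_OPERATION_SUCCESS:
            raise FormatError(f"reaction id {r.id!r} is not a valid SBML identifier")
        rx.setName(r.name)
        rx.setReversible(r.reversible)
        rx.setFast(False)
        for mid, c in r.stoichiometry.items():
            c = float(c)
            sr = rx.createReactant() if c < 0 else rx.createProduct()
            sr.setSpecies(mid)
            sr.setStoichiometry(abs(c))
            sr.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower_bound))
        rplug.setUpperFluxBound(bound_param(r.upper_bound))
        if r.gene_rule is not None:
            infix = r.gene_rule.expression
            for label, gpid in label_to_id.items():
                infix = re.sub(rf"\b{re.escape(label)}\b", gpid, infix)
            gpa = rplug.createGeneProductAssociation()
            rc = gpa.setAssociation(infix, True, False)
            _check_call(rc, f"GPR of {r.id}")

    if model.biomass_reaction is not None:
        objective = mplug.createObjective()
        objective.setId("obj")
        objective.setType("maximize")
        fo = objective.createFluxObjective()
        fo.setReaction(model.biomass_reaction)
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    return libsbml.writeSBMLToString(doc)


def write_model(model: MetabolicModel, format: str, path) -> List[Path]:
    """Serialize a model; returns the file paths written.

    ``format`` is one of ``"sbml"``, ``"flat"`` (path = directory) or
    ``"metatool"``.  Output is re-readable by the matching reader; note the
    Metatool dialect cannot carry numeric bounds, GPRs or the biomass flag.
    """
    if format == "flat":
        return _write_flat(model, path)
    if format == "sbml":
        _write_text(path, _format_sbml(model))
        return [Path(path)]
    if format == "metatool":
        _write_text(path, _format_metatool(model))
        return [Path(path)]
    raise ValueError(f"unknown format {format!r}; use 'sbml', 'flat' or 'metatool'")


# ---------------------------------------------------------------------------
# external / biomass auto-detection


@dataclass(frozen=True)
class DetectionReport:
    """Advisory detection of external species and biomass candidates.

    ``externals`` maps metabolite id to the evidence that flagged it
    (explicit, compartment or name-pattern); ``biomass_candidates`` is
    ranked best-first.  The caller decides whether to apply it (see
    :func:`apply_detection`).
    """

    externals: Dict[str, str] = field(default_factory=dict)
    biomass_candidates: List[Tuple[str, str]] = field(default_factory=list)


def detect_externals_and_biomass(
    model: MetabolicModel,
    explicit_externals: Optional[Set[str]] = None,
    name_patterns: Optional[Sequence[str]] = None,
) -> DetectionReport:
    """Guess external metabolites and biomass reactions from ids and names.

    Externals: the explicit set, plus species in an external compartment
    (``e``/``ext``/``extracellular``/``b`` by default), plus ids ending in a
    recognized suffix (``xt``, ``_ext``, ``[e]``).  Biomass candidates are
    reactions whose id or name contains a growth-related pattern, ranked by
    pattern priority.
    """
    explicit = set(explicit_externals or set())
    unknown = explicit - set(model.metabolites)
    if unknown:
        raise ModelError(f"explicit externals not in model: {sorted(unknown)}")
    suffixes = tuple(name_patterns) if name_patterns else config.EXTERNAL_NAME_SUFFIXES

    externals: Dict[str, str] = {}
    for m in model.metabolites.values():
        if m.id in explicit or m.external:
            externals[m.id] = "explicit"
        elif m.compartment is not None and m.compartment.lower() in config.EXTERNAL_COMPARTMENTS:
            externals[m.id] = "compartment"
        elif any(m.id.endswith(s) for s in suffixes):
            externals[m.id] = "name-pattern"

    candidates: List[Tuple[int, int, str, str]] = []
    for r in model.reactions.values():
        hay = f"{r.id} {r.name}".lower()
        for prio, pat in enumerate(config.BIOMASS_PATTERNS):
            if pat in hay:
                exact = 0 if r.id.lower() == pat or r.name.lower() == pat else 1
                candidates.append((exact, prio, r.id, "name-pattern"))
                break
    candidates.sort()
    return DetectionReport(
        externals=externals,
        biomass_candidates=[(rid, ev) for _, _, rid, ev in candidates],
    )


def apply_detection(model: MetabolicModel, report: DetectionReport) -> MetabolicModel:
    """Return a model with the report's externals and top biomass applied."""
    mets = [
        Metabolite(
            id=m.id, name=m.name, compartment=m.compartment,
            external=m.external or m.id in report.externals,
        )
        for m in model.metabolites.values()
    ]
    biomass = model.biomass_reaction
    if biomass is None and report.biomass_candidates:
        biomass = report.biomass_candidates[0][0]
    return MetabolicModel(
        metabolites=mets,
        reactions=[r.copy() for r in model.reactions.values()],
        biomass_reaction=biomass,
        genes=set(model.genes),
        name=model.name,
    )
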