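"""Tumor-microenvironment hierarchy: declaration, validation, mask compilation.

The hierarchy is a five-layer view of the tumor microenvironment (TME):

    genes -> cellular components -> cell types -> immune roles -> outcome

Each cell type carries an immune role (immunostimulatory or immunosuppressive)
and up to three *cellular components* — groups of marker proteins classified
as surface, secreted, or intracellular/transcription factor.  Marker genes
attach to components; components attach to their cell; cells attach to their
role.  Compiling a :class:`HierarchySpec` yields a :class:`MaskSet` of binary
adjacency matrices that constrain which network weights exist: an edge is
trainable iff its mask entry is 1.  The role layer connects densely to the
output layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

#: The three admissible cellular-component categories, in canonical order.
COMPONENT_CATEGORIES: tuple[str, ...] = ("surface", "secreted", "intracellular_tf")

#: The two immune roles, in canonical order (stimulatory first).
ROLES: tuple[str, ...] = ("immunostimulatory", "immunosuppressive")

#: Separator joining cell name and category into a component identifier.
COMPONENT_SEP = "::"

#: File suffixes of the three-matrix tabular config dialect.
MATRIX_SUFFIXES = (".gene_component.tsv", ".component_cell.tsv", ".cell_role.tsv")


class HierarchyError(ValueError):
    """Raised when a hierarchy spec or config file violates its contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellSpec:
    """One cell type: its immune role and marker genes per component category.

    Parameters
    ----------
    name:
        Unique cell-type identifier, e.g. ``"Th1"``.
    role:
        ``"immunostimulatory"`` or ``"immunosuppressive"``.
    markers:
        Mapping from component category (a member of
        :data:`COMPONENT_CATEGORIES`) to a non-empty sequence of gene symbols.
        Categories absent from the mapping contribute no component node.
    """

    name: str
    role: str
    markers: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "markers",
            {c: tuple(g for g in gs) for c, gs in dict(self.markers).items()},
        )

    def categories(self) -> tuple[str, ...]:
        """Component categories this cell declares, in canonical order."""
        return tuple(c for c in COMPONENT_CATEGORIES if c in self.markers)

    def genes(self) -> tuple[str, ...]:
        """All marker genes of this cell, category-major, duplicates kept."""
        return tuple(g for c in self.categories() for g in self.markers[c])


@dataclass(frozen=True)
class HierarchySpec:
    """A full TME hierarchy: an ordered collection of cell types."""

    cells: tuple[CellSpec, ...]
    name: str = "unnamed"

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(self.cells))

    # -- deterministic index orderings -------------------------------------
    def cell_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.cells)

    def component_ids(self) -> tuple[str, ...]:
        """Component identifiers ``cell::category``, cells in declaration
        order, categories in the fixed canonical order within each cell."""
        return tuple(
            f"{c.name}{COMPONENT_SEP}{cat}" for c in self.cells for cat in c.categories()
        )

    def gene_universe(self) -> tuple[str, ...]:
        """Distinct marker genes in first-appearance order.

        A gene listed by several cells or components is a single node.
        """
        seen: dict[str, None] = {}
        for cell in self.cells:
            for g in cell.genes():
                seen.setdefault(g, None)
        return tuple(seen)

    def get_cell(self, name: str) -> CellSpec:
        for c in self.cells:
            if c.name == name:
                return c
        raise HierarchyError(f"unknown cell {name!r}; known: {list(self.cell_names())}")


@dataclass
class MaskSet:
    """Binary adjacency matrices compiled from a :class:`HierarchySpec`.

    ``gene_component`` is genes x components, ``component_cell`` components x
    cells, ``cell_role`` cells x 2, and ``role_output`` the dense all-ones
    2 x n_out block.  Label tuples give the deterministic row/column index
    orderings shared with the spec.
    """

    gene_component: np.ndarray
    component_cell: np.ndarray
    cell_role: np.ndarray
    role_output: np.ndarray
    genes: tuple[str, ...]
    components: tuple[str, ...]
    cells: tuple[str, ...]
    roles: tuple[str, ...] = field(default=ROLES)

    @property
    def layer_sizes(self) -> tuple[int, int, int, int, int]:
        """(n_genes, n_components, n_cells, n_roles, n_out)."""
        return (
            len(self.genes),
            len(self.components),
            len(self.cells),
            len(self.roles),
            self.role_output.shape[1],
        )

    def sparse_masks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.gene_component, self.component_cell, self.cell_role

    def all_masks(self) -> tuple[np.ndarray, ...]:
        return (self.gene_component, self.component_cell, self.cell_role, self.role_output)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_spec(spec: HierarchySpec) -> list[str]:
    """Collect every invariant violation of *spec*; empty list means valid.

    Violations are returned as human-readable strings rather than raised, so
    callers (e.g. the CLI validator) can report all of them at once.
    """
    violations: list[str] = []
    seen_cells: set[str] = set()
    for cell in spec.cells:
        if not cell.name or not isinstance(cell.name, str):
            violations.append(f"cell name must be a non-empty string, got {cell.name!r}")
        if cell.name in seen_cells:
            violations.append(f"duplicate cell name {cell.name!r}")
        seen_cells.add(cell.name)
        if cell.role not in ROLES:
            violations.append(
                f"cell {cell.name!r}: role {cell.role!r} not in {list(ROLES)}"
            )
        if not cell.markers:
            violations.append(f"cell {cell.name!r}: no component categories declared")
        for cat, genes in cell.markers.items():
            if cat not in COMPONENT_CATEGORIES:
                violations.append(
                    f"cell {cell.name!r}: unknown component category {cat!r}"
                    f" (admissible: {list(COMPONENT_CATEGORIES)})"
                )
                continue
            if len(genes) == 0:
                violations.append(f"cell {cell.name!r}: component {cat!r} has no marker genes")
            if any((not g) or (not isinstance(g, str)) for g in genes):
                violations.append(
                    f"cell {cell.name!r}: component {cat!r} has an empty gene identifier"
                )
            dupes = {g for g in genes if genes.count(g) > 1}
            if dupes:
                violations.append(
                    f"cell {cell.name!r}: component {cat!r} lists duplicate genes {sorted(dupes)}"
                )
    if not spec.cells:
        violations.append("spec declares no cells")
    for role in ROLES:
        if spec.cells and not any(c.role == role for c in spec.cells):
            violations.append(f"no {role} cell (role layer would be degenerate)")
    return violations


def _require_valid(spec: HierarchySpec) -> None:
    violations = validate_spec(spec)
    if violations:
        raise HierarchyError(f"invalid hierarchy spec: {violations[0]}")


# ---------------------------------------------------------------------------
# Mask compilation
# ---------------------------------------------------------------------------


def build_masks(spec: HierarchySpec, n_out: int = 1) -> MaskSet:
    """Compile *spec* into the binary mask matrices of the sparse network.

    A 1 appears exactly where the spec declares a membership; the role-to-
    output block is dense (all ones).  Raises :class:`HierarchyError` naming
    the first violation if the spec is invalid.
    """
    _require_valid(spec)
    genes = spec.gene_universe()
    components = spec.component_ids()
    cells = spec.cell_names()
    g_idx = {g: i for i, g in enumerate(genes)}
    k_idx = {k: i for i, k in enumerate(components)}

    gene_component = np.zeros((len(genes), len(components)))
    component_cell = np.zeros((len(components), len(cells)))
    cell_role = np.zeros((len(cells), len(ROLES)))
    for j, cell in enumerate(spec.cells):
        cell_role[j, ROLES.index(cell.role)] = 1.0
        for cat in cell.categories():
            k = k_idx[f"{cell.name}{COMPONENT_SEP}{cat}"]
            component_cell[k, j] = 1.0
            for g in cell.markers[cat]:
                gene_component[g_idx[g], k] = 1.0
    role_output = np.ones((len(ROLES), n_out))
    return MaskSet(gene_component, component_cell, cell_role, role_output,
                   genes=genes, components=components, cells=cells)


def count_parameters(spec: HierarchySpec, with_biases: bool = True, n_out: int = 1) -> int:
    """Number of learnable parameters of the masked network built from *spec*.

    Counts one parameter per active edge (mask entry 1) in the three sparse
    layers, plus the ``n_roles * n_out`` dense role-to-output edges, plus —
    when *with_biases* — one bias per non-input node (components, cells,
    roles, outputs).  The bias/output conventions are exposed rather than
    fixed because published parameter totals for networks of this family are
    sensitive to both.
    """
    masks = build_masks(spec, n_out=n_out)
    edges = int(sum(m.sum() for m in masks.all_masks()))
    if with_biases:
        _, n_comp, n_cells, n_roles, n_o = masks.layer_sizes
        edges += n_comp + n_cells + n_roles + n_o
    return edges


# ---------------------------------------------------------------------------
# Ablation support
# ---------------------------------------------------------------------------


def remove_cell(
    spec: HierarchySpec, cell_name: str, allow_empty_role: bool = False
) -> HierarchySpec:
    """Return a new spec lacking *cell_name*, its components, and its
    exclusive genes.

    Genes shared with surviving cells are retained (they remain nodes with at
    least one active edge).  By default removal must leave at least one cell
    in each role; pass ``allow_empty_role=True`` to permit a role node with
    zero inbound edges, as full-role ablation studies require.
    """
    spec.get_cell(cell_name)  # raises on unknown name
    survivors = tuple(c for c in spec.cells if c.name != cell_name)
    if not allow_empty_role:
        for role in ROLES:
            if not any(c.role == role for c in survivors):
                raise HierarchyError(
                    f"removing {cell_name!r} would empty the {role} role; "
                    "pass allow_empty_role=True to permit this"
                )
    return HierarchySpec(cells=survivors, name=spec.name)


# ---------------------------------------------------------------------------
# Config I/O — canonical structured document (YAML)
# ---------------------------------------------------------------------------


def write_config(spec: HierarchySpec, path: str | Path) -> None:
    """Write *spec* as the canonical structured-text hierarchy document."""
    doc = {
        "name": spec.name,
        "cells": [
            {
                "name": c.name,
                "role": c.role,
                "markers": {cat: list(c.markers[cat]) for cat in c.categories()},
            }
            for c in spec.cells
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_config(path: str | Path) -> HierarchySpec:
    """Read a hierarchy from either supported dialect.

    A path ending in one of the three-matrix suffixes (or a bare prefix for
    which ``<prefix>.gene_component.tsv`` exists) selects the tabular
    dialect; anything else is parsed as the structured document.
    """
    p = Path(path)
    for suffix in MATRIX_SUFFIXES:
        if p.name.endswith(suffix):
            return read_matrix_config(str(p)[: -len(suffix)])
    if not p.exists() and Path(str(p) + MATRIX_SUFFIXES[0]).exists():
        return read_matrix_config(p)
    try:
        doc = yaml.safe_load(p.read_text())
    except yaml.YAMLError as e:
        raise HierarchyError(f"{p}: malformed document: {e}") from e
    if not isinstance(doc, dict) or "cells" not in doc:
        raise HierarchyError(f"{p}: missing top-level 'cells' field")
    cells = []
    for i, entry in enumerate(doc["cells"]):
        for key in ("name", "role", "markers"):
            if key not in entry:
                raise HierarchyError(f"{p}: cells[{i}] missing field {key!r}")
        markers = {
            cat: tuple(str(g).strip() for g in genes)
            for cat, genes in entry["markers"].items()
        }
        cells.append(CellSpec(name=entry["name"], role=entry["role"], markers=markers))
    spec = HierarchySpec(cells=tuple(cells), name=doc.get("name", "unnamed"))
    violations = validate_spec(spec)
    if violations:
        raise HierarchyError(f"{p}: {violations[0]}")
    return spec


# ---------------------------------------------------------------------------
# Config I/O — three-matrix tabular dialect
# ---------------------------------------------------------------------------


def _write_matrix(path: Path, mat: np.ndarray, rows: Sequence[str], cols: Sequence[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["", *cols]) + "\n")
        for label, row in zip(rows, mat):
            fh.write("\t".join([label, *(str(int(v)) for v in row)]) + "\n")


def _read_matrix(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    lines = path.read_text().splitlines()
    if not lines:
        raise HierarchyError(f"{path}: empty file")
    cols = lines[0].split("\t")[1:]
    rows, body = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(cols) + 1:
            raise HierarchyError(
                f"{path}:{lineno}: expected {len(cols) + 1} fields, got {len(parts)}"
            )
        rows.append(parts[0])
        try:
            vals = [int(v) for v in parts[1:]]
        except ValueError as e:
            raise HierarchyError(f"{path}:{lineno}: non-integer entry ({e})") from e
        if any(v not in (0, 1) for v in vals):
            raise HierarchyError(f"{path}:{lineno}: entries must be 0 or 1")
        body.append(vals)
    return np.asarray(body, dtype=float), rows, cols


def write_matrix_config(spec: HierarchySpec, prefix: str | Path) -> list[Path]:
    """Write the three-matrix tabular dialect under ``<prefix>.*.tsv``."""
    masks = build_masks(spec)
    prefix = str(prefix)
    paths = [Path(prefix + s) for s in MATRIX_SUFFIXES]
    _write_matrix(paths[0], masks.gene_component, masks.genes, masks.components)
    _write_matrix(paths[1], masks.component_cell, masks.components, masks.cells)
    _write_matrix(paths[2], masks.cell_role, masks.cells, masks.roles)
    return paths


def read_matrix_config(prefix: str | Path) -> HierarchySpec:
    """Reconstruct a :class:`HierarchySpec` from the three-matrix dialect.

    Component identifiers must have the ``cell::category`` form so the cell
    structure can be recovered; membership invariants (each component in
    exactly one cell, each cell in exactly one role) are enforced here.
    """
    prefix = str(prefix)
    gc, gc_rows, gc_cols = _read_matrix(Path(prefix + MATRIX_SUFFIXES[0]))
    ck, ck_rows, ck_cols = _read_matrix(Path(prefix + MATRIX_SUFFIXES[1]))
    cr, cr_rows, cr_cols = _read_matrix(Path(prefix + MATRIX_SUFFIXES[2]))
    if gc_cols != ck_rows:
        raise HierarchyError(
            f"{prefix}: component labels disagree between gene_component columns "
            f"and component_cell rows"
        )
    if ck_cols != cr_rows:
        raise HierarchyError(
            f"{prefix}: cell labels disagree between component_cell columns and cell_role rows"
        )
    if list(cr_cols) != list(ROLES):
        raise HierarchyError(f"{prefix}: cell_role columns must be {list(ROLES)}, got {cr_cols}")
    for i, comp in enumerate(ck_rows):
        if int(ck[i].sum()) != 1:
            raise HierarchyError(
                f"{prefix}: component {comp!r} must belong to exactly one cell "
                f"(row sum {int(ck[i].sum())})"
            )
    cells = []
    for j, cell_name in enumerate(ck_cols):
        if int(cr[j].sum()) != 1:
            raise HierarchyError(
                f"{prefix}: cell {cell_name!r} must have exactly one role "
                f"(row sum {int(cr[j].sum())})"
            )
        role = ROLES[int(np.argmax(cr[j]))]
        markers: dict[str, tuple[str, ...]] = {}
        for k, comp in enumerate(ck_rows):
            if ck[k, j] != 1:
                continue
            if COMPONENT_SEP not in comp:
                raise HierarchyError(
                    f"{prefix}: component label {comp!r} lacks the "
                    f"'cell{COMPONENT_SEP}category' form"
                )
            cat = comp.split(COMPONENT_SEP, 1)[1]
            genes = tuple(g for g, row in zip(gc_rows, gc[:, k]) if row == 1)
            if not genes:
                raise HierarchyError(f"{prefix}: component {comp!r} has no marker genes")
            markers[cat] = genes
        cells.append(CellSpec(name=cell_name, role=role, markers=markers))
    spec = HierarchySpec(cells=tuple(cells), name=Path(prefix).name)
    violations = validate_spec(spec)
    if violations:
        raise HierarchyError(f"{prefix}: {violations[0]}")
    return spec


# ---------------------------------------------------------------------------
# Default hierarchy
# ---------------------------------------------------------------------------


def default_hierarchy() -> HierarchySpec:
    """The shipped nine-cell TME hierarchy.

    Five immunostimulatory cell types (M1 macrophages, dendritic cells,
    CD8+ effector T cells, Th1 cells, NK cells) and four immunosuppressive
    ones (M2 macrophages, MDSCs, Tregs, Th2 cells), each with surface,
    secreted, and transcription-factor components: 2 roles, 9 cells, 27
    components.  Marker genes are an illustrative, non-curated selection of
    well-known immunology symbols (two per component); real analyses should
    supply their own curated hierarchy document.
    """
    s, k, t = COMPONENT_CATEGORIES
    stim, supp = ROLES
    return HierarchySpec(
        name="tme-default",
        cells=(
            CellSpec("M1_macrophage", stim, {s: ("CD80", "CD86"), k: ("IL12B", "TNF"), t: ("NFKB1", "STAT1")}),
            CellSpec("Dendritic_cell", stim, {s: ("CD1C", "ITGAX"), k: ("IL12A", "CXCL9"), t: ("BATF3", "IRF8")}),
            CellSpec("CD8_effector", stim, {s: ("CD8A", "CD8B"), k: ("GZMB", "PRF1"), t: ("EOMES", "RUNX3")}),
            CellSpec("Th1", stim, {s: ("CXCR3", "IL12RB2"), k: ("IFNG", "IL2"), t: ("STAT4", "TBX21")}),
            CellSpec("NK", stim, {s: ("NCAM1", "KLRD1"), k: ("GZMA", "XCL1"), t: ("ID2", "NFIL3")}),
            CellSpec("M2_macrophage", supp, {s: ("MRC1", "CD163"), k: ("ARG1", "IL10"), t: ("IRF4", "MAF")}),
            CellSpec("MDSC", supp, {s: ("ITGAM", "FUT4"), k: ("NOS2", "S100A8"), t: ("CEBPB", "STAT3")}),
            CellSpec("Treg", supp, {s: ("IL2RA", "CTLA4"), k: ("TGFB1", "EBI3"), t: ("FOXP3", "IKZF2")}),
            CellSpec("Th2", supp, {s: ("CCR4", "IL4R"), k: ("IL4", "IL13"), t: ("GATA3", "STAT6")}),
        ),
    )
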