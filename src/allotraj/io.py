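"""File IO: TPS landmark files, metadata tables, Newick trees, matrices.

TPS dialect: each record starts with ``LM=<k>`` (2D) or ``LM3=<k>`` (3D),
followed by ``k`` whitespace-separated coordinate lines, then key=value
lines (``ID=`` required, ``SCALE=`` optional and applied multiplicatively).
"""

from __future__ import annotations

import logging
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .dataset import LandmarkDataset, SpecimenRecord

logger = logging.getLogger("allotraj")

_COUNTS_RESOURCE = "cercopithecid_counts.csv"


class TPSParseError(ValueError):
    pass


def read_tps(path) -> LandmarkDataset:
    """Parse a TPS landmark file into a :class:`LandmarkDataset`.

    Metadata fields (species, sex) are left empty; use
    :func:`join_metadata` to annotate from a table.
    """
    lines = Path(path).read_text().splitlines()
    records: list[SpecimenRecord] = []
    dims: set[int] = set()
    i, n_rec = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        upper = line.upper()
        if not (upper.startswith("LM=") or upper.startswith("LM3=")):
            raise TPSParseError(f"{path}: expected LM=/LM3= at line {i + 1}, got {line!r}")
        n_rec += 1
        d = 3 if upper.startswith("LM3=") else 2
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(f"{path}: bad landmark count at line {i + 1}") from exc
        i += 1
        coords = []
        while i < len(lines) and len(coords) < k:
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if "=" in row and not _is_numeric_row(row):
                break  # hit the next keyword early: too few coordinate lines
            vals = row.split()
            if len(vals) != d:
                raise TPSParseError(
                    f"{path}: record {n_rec}: expected {d} values per coordinate "
                    f"line, got {len(vals)} at line {i + 1}"
                )
            coords.append([float(v) for v in vals])
            i += 1
        if len(coords) != k:
            raise TPSParseError(
                f"{path}: record {n_rec}: LM={k} but only {len(coords)} coordinate lines"
            )
        spec_id, scale = None, None
        while i < len(lines):
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if row.upper().startswith(("LM=", "LM3=")):
                break
            if "=" not in row:
                raise TPSParseError(
                    f"{path}: record {n_rec}: unexpected extra line {row!r} at line {i + 1}"
                )
            key, _, value = row.partition("=")
            key = key.strip().upper()
            if key == "ID":
                spec_id = value.strip()
            elif key == "SCALE":
                scale = float(value)
            i += 1
        if spec_id is None:
            raise TPSParseError(f"{path}: record {n_rec}: missing ID= line")
        arr = np.asarray(coords, dtype=float)
        if scale is not None:
            arr = arr * scale
        dims.add(d)
        if len(dims) > 1:
            raise TPSParseError(f"{path}: mixed 2D/3D records (LM= and LM3=)")
        records.append(SpecimenRecord(specimen_id=spec_id, coords=arr))
    if not records:
        raise TPSParseError(f"{path}: no records found")
    return LandmarkDataset(records)


def _is_numeric_row(row: str) -> bool:
    try:
        [float(v) for v in row.split()]
        return True
    except ValueError:
        return False


def write_tps(dataset: LandmarkDataset, path) -> None:
    """Write a dataset in TPS format (coordinates at 1e-9 precision)."""
    with open(path, "w") as fh:
        for rec in dataset:
            fh.write(f"LM{'3' if rec.d == 3 else ''}={rec.k}\n")
            for point in rec.coords:
                fh.write(" ".join(f"{v:.9f}" for v in point) + "\n")
            fh.write(f"ID={rec.specimen_id}\n")


def read_metadata(path) -> pd.DataFrame:
    """Read a specimen metadata CSV (columns specimen_id, species, sex; extras kept)."""
    table = pd.read_csv(path, dtype=str)
    missing = {"specimen_id", "species", "sex"} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    return table


def join_metadata(dataset: LandmarkDataset, table: pd.DataFrame) -> LandmarkDataset:
    """Annotate records with species/sex from a metadata table keyed by specimen_id.

    Genus is always derived from the species label. Duplicate metadata rows
    with identical content are accepted with a warning; conflicting
    duplicates are an error.
    """
    table = table.copy()
    required = {"specimen_id", "species", "sex"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns {sorted(missing_cols)}")
    dup_mask = table.duplicated(subset="specimen_id", keep=False)
    if dup_mask.any():
        full_dupes = table.duplicated(keep=False)
        conflicting = sorted(set(table.loc[dup_mask & ~full_dupes, "specimen_id"]))
        if conflicting:
            raise ValueError(f"conflicting duplicate metadata rows for ids: {conflicting}")
        logger.warning(
            "metadata: %d duplicate (identical) rows collapsed", int(table.duplicated().sum())
        )
        table = table.drop_duplicates(subset="specimen_id")
    meta = table.set_index("specimen_id")
    absent = [i for i in dataset.specimen_ids if i not in meta.index]
    if absent:
        raise KeyError(f"specimens missing from metadata: {absent}")
    extra_cols = [c for c in table.columns if c not in required]
    annotated = []
    for rec in dataset:
        row = meta.loc[rec.specimen_id]
        annotated.append(
            SpecimenRecord(
                specimen_id=rec.specimen_id,
                coords=rec.coords,
                species=str(row["species"]),
                sex=str(row["sex"]),
                extra={c: row[c] for c in extra_cols},
            )
        )
    return LandmarkDataset(annotated)


def filter_by_min_n(dataset: LandmarkDataset, sex: str, min_n: int) -> LandmarkDataset:
    """Keep records of one sex belonging to species with >= min_n specimens of that sex.

    The filter is applied independently per sex: a species may pass for
    females and fail for males.
    """
    if sex not in ("F", "M"):
        raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")
    counts = dataset.species_counts(sex=sex)
    kept_species = {s for s, c in counts.items() if c >= min_n}
    dropped = sorted(set(counts) - kept_species)
    indices = [
        i for i, rec in enumerate(dataset) if rec.sex == sex and rec.species in kept_species
    ]
    if not indices:
        raise ValueError(
            f"no {sex} records left at min_n={min_n}; lower the threshold "
            f"(species counts: {counts})"
        )
    logger.info(
        "filter_by_min_n(sex=%s, min_n=%d): retained %d species (%d specimens), dropped %d: %s",
        sex, min_n, len(kept_species), len(indices), len(dropped), dropped,
    )
    return dataset.subset(indices)


def normalize_label(label: str) -> str:
    return "_".join(str(label).strip().split())


def read_newick(path) -> dendropy.Tree:
    """Read a Newick chronogram; tip labels normalized to 'Genus_species'.

    Branch lengths are required on all non-root edges (time-calibrated
    tree expected).
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError(f"{path}: branch without length (chronogram required)")
    for taxon in tree.taxon_namespace:
        taxon.label = normalize_label(taxon.label)
    return tree


def match_taxa(species_list, tree: dendropy.Tree):
    """Prune a tree to the species present in both the list and the tips.

    Returns ``(pruned_tree, retained)`` with ``retained`` in the original
    list order. Dropped taxa on either side are logged as warnings.
    """
    species_list = list(species_list)
    tip_labels = {t.label for t in tree.taxon_namespace}
    retained = [s for s in species_list if s in tip_labels]
    if len(retained) < 3:
        raise ValueError(
            f"only {len(retained)} species shared between data and tree; "
            "phylogenetic-signal tests need at least 3"
        )
    dropped_species = sorted(set(species_list) - set(retained))
    dropped_tips = sorted(tip_labels - set(species_list))
    if dropped_species:
        logger.warning("species absent from tree, dropped: %s", dropped_species)
    if dropped_tips:
        logger.warning("tree tips absent from data, pruned: %s", dropped_tips)
    pruned = tree.clone(depth=1)
    if dropped_tips:
        pruned.retain_taxa_with_labels(retained)
    return pruned, retained


def load_survey_counts() -> pd.DataFrame:
    """Packaged museum-survey specimen counts per Old World monkey species and sex.

    Columns: tribe, species, n_female, n_male. These counts are the
    bookkeeping fixture used by the minimum-N filter tests.
    """
    from importlib.resources import files

    with files("allotraj.data").joinpath(_COUNTS_RESOURCE).open() as fh:
        return pd.read_csv(fh)


def counts_to_dataset(counts: pd.DataFrame, k: int = 6, d: int = 2) -> LandmarkDataset:
    """Expand a species x sex count table into a dataset of placeholder configurations.

    Coordinates are an arbitrary fixed non-degenerate configuration; only
    the metadata (species, sex, one record per counted specimen) matters,
    which is what the filtering bookkeeping operates on.
    """
    template = np.column_stack(
        [np.cos(np.linspace(0, 2 * np.pi, k, endpoint=False)),
         np.sin(np.linspace(0, 2 * np.pi, k, endpoint=False))]
    )
    if d == 3:
        template = np.column_stack([template, np.zeros(k)])
    records = []
    for _, row in counts.iterrows():
        for sex, col in (("F", "n_female"), ("M", "n_male")):
            for j in range(int(row[col])):
                records.append(
                    SpecimenRecord(
                        specimen_id=f"{row['species']}_{sex}{j:04d}",
                        coords=template,
                        species=row["species"],
                        sex=sex,
                    )
                )
    return LandmarkDataset(records)


def write_square_matrix(labels, matrix: np.ndarray, path) -> None:
    pd.DataFrame(matrix, index=list(labels), columns=list(labels)).to_csv(path)


def read_square_matrix(path):
    df = pd.read_csv(path, index_col=0)
    return list(df.index), df.to_numpy(dtype=float)
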