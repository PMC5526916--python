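"""Domain containers and file formats for SSR germplasm analyses.

The central container is :class:`GenotypeMatrix`: diploid codominant
microsatellite calls (allele sizes in base pairs) for individuals grouped
into accessions.  Readers/writers cover the tabular dialects the pipeline
touches (wide/long CSV, GENEPOP 3-digit, STRUCTURE one-row) plus Q-matrix
text files from model-based clustering runs, PHYLIP square distance
matrices and Newick trees.

Allele codes are the scored fragment sizes themselves (positive integers),
never recoded indices; GENEPOP export recodes sizes above 999 bp through an
explicit persisted mapping.  A locus call is either two alleles or wholly
missing — half-calls are scoring artifacts and are rejected at parse time
(GENEPOP's in-band half-missing codes are demoted to wholly missing).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "AccessionMetadata",
    "QRunSet",
    "PhaseolinCall",
    "TraitTable",
    "ParseError",
    "read_genotype_table",
    "write_interchange",
    "read_q_runs",
    "write_q_run",
    "write_phylip_distance",
    "write_newick",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending row/line."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    """Diploid allele-size calls for individuals grouped into accessions.

    Parameters
    ----------
    individuals : list of str
        Ordered individual ids (unique).
    loci : list of str
        Ordered locus names.
    accession_of : dict
        Maps every individual id to its accession id.
    alleles : ndarray of shape (n_individuals, n_loci, 2)
        Integer allele sizes in bp; both entries ``MISSING`` (−1) for a
        missing call.  Half-calls (exactly one −1) are invalid.
    """

    individuals: list[str]
    loci: list[str]
    accession_of: dict[str, str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n, L = len(self.individuals), len(self.loci)
        if n < 1 or L < 1:
            raise ValueError("need at least one individual and one locus")
        if len(set(self.individuals)) != n:
            raise ValueError("duplicate individual ids")
        if self.alleles.shape != (n, L, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} != ({n}, {L}, 2)"
            )
        missing = self.alleles == MISSING
        half = missing[..., 0] ^ missing[..., 1]
        if half.any():
            i, l = np.argwhere(half)[0]
            raise ValueError(
                f"half-call at individual {self.individuals[i]!r}, "
                f"locus {self.loci[l]!r}"
            )
        if ((self.alleles <= 0) & ~missing).any():
            raise ValueError("allele codes must be positive integers")
        for ind in self.individuals:
            if ind not in self.accession_of:
                raise ValueError(f"individual {ind!r} has no accession")

    # -- convenience -------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def accessions(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.accession_of[ind], None)
        return list(seen)

    def members(self, accession: str) -> list[str]:
        return [i for i in self.individuals if self.accession_of[i] == accession]

    def indices_of(self, accession: str) -> np.ndarray:
        return np.array(
            [k for k, i in enumerate(self.individuals)
             if self.accession_of[i] == accession],
            dtype=int,
        )

    def subset(self, individuals: list[str]) -> "GenotypeMatrix":
        idx = [self.individuals.index(i) for i in individuals]
        return GenotypeMatrix(
            individuals=list(individuals),
            loci=list(self.loci),
            accession_of={i: self.accession_of[i] for i in individuals},
            alleles=self.alleles[idx].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and self.accession_of == other.accession_of
            and np.array_equal(self.alleles, other.alleles)
        )


@dataclass(frozen=True)
class AccessionMetadata:
    """Passport data for one accession."""

    accession: str
    region: str
    latitude: float | None = None
    longitude: float | None = None
    group: str = "landrace"  # landrace | race-representative | wild

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if self.longitude is not None and not -180 <= self.longitude <= 180:
            raise ValueError(f"longitude out of range: {self.longitude}")


@dataclass
class QRunSet:
    """Admixture runs: run id -> (K, lnP, Q matrix over individuals).

    Each run is a dict ``{"K": int, "lnP": float, "Q": {ind: ndarray}}``;
    every Q vector lies on the length-K simplex and all runs at a given K
    share the same individual set.
    """

    runs: dict[str, dict] = field(default_factory=dict)

    def add(self, run_id: str, K: int, lnP: float,
            Q: dict[str, np.ndarray]) -> None:
        for ind, q in Q.items():
            q = np.asarray(q, dtype=float)
            if q.shape != (K,):
                raise ValueError(f"Q vector for {ind!r} has length {q.size}, expected {K}")
            if (q < 0).any() or abs(q.sum() - 1.0) > 1e-4:
                raise ValueError(f"Q row for {ind!r} is not on the simplex: {q}")
            Q[ind] = q / q.sum()
        same_k = [r for r in self.runs.values() if r["K"] == K]
        if same_k and set(same_k[0]["Q"]) != set(Q):
            raise ValueError(f"individual sets differ among runs at K={K}")
        self.runs[run_id] = {"K": K, "lnP": float(lnP), "Q": Q}

    def ks(self) -> list[int]:
        return sorted({r["K"] for r in self.runs.values()})

    def runs_at(self, K: int) -> list[dict]:
        return [r for r in self.runs.values() if r["K"] == K]

    def best_run(self, K: int) -> dict:
        """The maximum-likelihood run at K (ties: first encountered)."""
        runs = self.runs_at(K)
        if not runs:
            raise KeyError(f"no runs at K={K}")
        return max(runs, key=lambda r: r["lnP"])


@dataclass(frozen=True)
class PhaseolinCall:
    """Phaseolin PCR fragment pattern and its haplotype label for one plant."""

    individual: str
    fragments: tuple[int, ...]
    haplotype: str = "other"  # P1 | P2 | P3 | other

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fragments):
            raise ValueError("fragment lengths must be positive")


QUALITATIVE_STATES = {
    "growth_habit": ["determinate", "indeterminate"],
    "seed_shape": ["round", "oval", "cuboid", "kidney"],
    "seed_coat_pattern": [
        "absent", "spotted_bicolor", "speckled_marginal", "striped",
        "mottled", "broad_striped", "colored_around_hilum",
    ],
    # 8 named colors + "patterned" placeholder for patterned coats,
    # so the five core-collection traits total 25 states
    "seed_coat_color": [
        "white", "yellow", "pink", "light_brown", "brown", "red",
        "purplish_red", "black", "patterned",
    ],
    "seed_size": ["small", "medium", "large"],
}

QUANTITATIVE_TRAITS = [
    "seed_length_mm", "seed_width_mm", "seed_height_mm",
    "weight_100seed_g", "seeds_per_pod", "locules_per_pod",
    "elongation", "flatness", "flatness_index",
]


@dataclass
class TraitTable:
    """Per-accession morphology: 9 quantitative + 5 qualitative traits.

    ``data`` is a DataFrame indexed by accession id with the columns in
    :data:`QUANTITATIVE_TRAITS` and :data:`QUALITATIVE_STATES`.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("seed_length_mm", "seed_width_mm", "seed_height_mm",
                    "weight_100seed_g"):
            if col in self.data and (self.data[col].dropna() <= 0).any():
                raise ValueError(f"nonpositive values in {col}")
        for col, states in QUALITATIVE_STATES.items():
            if col in self.data:
                bad = set(self.data[col].dropna()) - set(states)
                if bad:
                    raise ValueError(f"unknown states in {col}: {sorted(bad)}")

    @property
    def accessions(self) -> list[str]:
        return list(self.data.index)


# ---------------------------------------------------------------------------
# genotype table readers


def _parse_allele(token: str, where: str) -> int:
    token = token.strip()
    if token in ("", "NA", "na", "-", "?"):
        return MISSING
    try:
        val = int(token)
    except ValueError:
        raise ParseError(f"non-integer allele {token!r} at {where}") from None
    if val == 0:
        return MISSING
    if val < 0:
        raise ParseError(f"negative allele {token!r} at {where}")
    return val


def _finalize_call(a: int, b: int, where: str, *, demote_half: bool = False) -> tuple[int, int]:
    if (a == MISSING) != (b == MISSING):
        if demote_half:
            return (MISSING, MISSING)
        raise ParseError(f"half-call at {where}")
    return (a, b)


def read_genotype_table(path: str | Path, dialect: str = "wide") -> GenotypeMatrix:
    """Read a genotype table.

    dialect ``wide``: one row per individual, columns
    ``individual, accession, <locus>.1, <locus>.2, ...``.
    dialect ``long``: columns ``individual, accession, locus, allele1, allele2``.
    dialect ``genepop``: GENEPOP text with 3-digit allele codes.
    """
    if dialect == "wide":
        return _read_wide(Path(path))
    if dialect == "long":
        return _read_long(Path(path))
    if dialect == "genepop":
        return _read_genepop(Path(path))
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_wide(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if cols[:2] != ["individual", "accession"]:
        raise ParseError(f"{path}: wide dialect needs leading "
                         "'individual,accession' columns")
    locus_cols = cols[2:]
    if len(locus_cols) % 2:
        raise ParseError(f"{path}: odd number of allele columns")
    loci = []
    for i in range(0, len(locus_cols), 2):
        a, b = locus_cols[i], locus_cols[i + 1]
        la, lb = a.rsplit(".", 1)[0], b.rsplit(".", 1)[0]
        if la != lb:
            raise ParseError(f"{path}: allele columns {a!r}/{b!r} do not pair")
        loci.append(la)
    individuals, accession_of = [], {}
    alleles = np.full((len(df), len(loci), 2), MISSING, dtype=np.int64)
    for r, row in enumerate(df.itertuples(index=False), start=2):
        ind, acc = row[0], row[1]
        if ind in accession_of:
            raise ParseError(f"{path}:{r}: duplicate individual id {ind!r}")
        individuals.append(ind)
        accession_of[ind] = acc
        for l, locus in enumerate(loci):
            where = f"{path}:{r} locus {locus}"
            a = _parse_allele(row[2 + 2 * l], where)
            b = _parse_allele(row[3 + 2 * l], where)
            alleles[r - 2, l] = _finalize_call(a, b, where)
    return GenotypeMatrix(individuals, loci, accession_of, alleles)


def _read_long(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    need = ["individual", "accession", "locus", "allele1", "allele2"]
    if list(df.columns) != need:
        raise ParseError(f"{path}: long dialect needs columns {need}")
    extra = [c for c in df.columns if c not in need]
    if extra:
        raise ParseError(f"{path}: unexpected columns {extra} (three allele "
                         "fields for one locus?)")
    loci: list[str] = []
    for locus in df["locus"]:
        if locus not in loci:
            loci.append(locus)
    individuals: list[str] = []
    accession_of: dict[str, str] = {}
    for ind, acc in zip(df["individual"], df["accession"]):
        if ind not in accession_of:
            individuals.append(ind)
            accession_of[ind] = acc
        elif accession_of[ind] != acc:
            raise ParseError(f"{path}: individual {ind!r} in two accessions")
    alleles = np.full((len(individuals), len(loci), 2), MISSING, dtype=np.int64)
    seen = set()
    for r, row in df.iterrows():
        key = (row["individual"], row["locus"])
        if key in seen:
            raise ParseError(f"{path}: duplicate call for {key}")
        seen.add(key)
        where = f"{path}: row {r + 2}"
        a = _parse_allele(row["allele1"], where)
        b = _parse_allele(row["allele2"], where)
        i = individuals.index(row["individual"])
        l = loci.index(row["locus"])
        alleles[i, l] = _finalize_call(a, b, where)
    return GenotypeMatrix(individuals, loci, accession_of, alleles)


def _read_genepop(path: Path) -> GenotypeMatrix:
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: truncated GENEPOP file")
    body = lines[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        loci.extend(t.strip() for t in body[i].split(",") if t.strip())
        i += 1
    if not loci:
        raise ParseError(f"{path}: no locus names before first Pop")
    individuals: list[str] = []
    accession_of: dict[str, str] = {}
    rows: list[list[tuple[int, int]]] = []
    pop_idx = 0
    while i < len(body):
        if body[i].strip().lower() == "pop":
            pop_idx += 1
            i += 1
            continue
        line = body[i].strip()
        i += 1
        if not line:
            continue
        if "," not in line:
            raise ParseError(f"{path}: line {i + 1}: missing ',' separator")
        ind, geno = line.split(",", 1)
        ind = ind.strip()
        if ind in accession_of:
            raise ParseError(f"{path}: duplicate individual id {ind!r}")
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise ParseError(
                f"{path}: line {i + 1}: {len(tokens)} genotypes for "
                f"{len(loci)} loci")
        calls = []
        for locus, tok in zip(loci, tokens):
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise ParseError(
                    f"{path}: line {i + 1}: bad genotype code {tok!r}")
            w = len(tok) // 2
            a, b = int(tok[:w]), int(tok[w:])
            a = MISSING if a == 0 else a
            b = MISSING if b == 0 else b
            # in-band half-missing codes are demoted to wholly missing
            calls.append(_finalize_call(a, b,
                                        f"{path}: line {i + 1} locus {locus}",
                                        demote_half=True))
        # accession from the shared "<acc>_<ordinal>" id convention,
        # falling back to the Pop block ordinal
        acc = ind.rsplit("_", 1)[0] if "_" in ind else f"pop{pop_idx}"
        individuals.append(ind)
        accession_of[ind] = acc
        rows.append(calls)
    if not individuals:
        raise ParseError(f"{path}: no individuals")
    return GenotypeMatrix(individuals, loci, accession_of,
                          np.array(rows, dtype=np.int64))


# ---------------------------------------------------------------------------
# writers


def write_interchange(geno: GenotypeMatrix, dialect: str,
                      path: str | Path) -> None:
    """Write ``geno`` in an interchange dialect.

    ``wide``/``long``: CSV round-trippable through :func:`read_genotype_table`.
    ``genepop``: 3-digit codes, one Pop block per accession.  Allele sizes
    above 999 bp raise with a pointer to :func:`write_genepop_recoded`.
    ``structure``: one row per individual, two columns per locus, −9 missing.
    """
    path = Path(path)
    if dialect == "wide":
        _write_wide(geno, path)
    elif dialect == "long":
        _write_long(geno, path)
    elif dialect == "genepop":
        _write_genepop(geno, path)
    elif dialect == "structure":
        _write_structure(geno, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_wide(geno: GenotypeMatrix, path: Path) -> None:
    cols = {"individual": geno.individuals,
            "accession": [geno.accession_of[i] for i in geno.individuals]}
    for l, locus in enumerate(geno.loci):
        for slot in (0, 1):
            vals = geno.alleles[:, l, slot]
            cols[f"{locus}.{slot + 1}"] = ["" if v == MISSING else str(v)
                                           for v in vals]
    pd.DataFrame(cols).to_csv(path, index=False)


def _write_long(geno: GenotypeMatrix, path: Path) -> None:
    rows = []
    for k, ind in enumerate(geno.individuals):
        for l, locus in enumerate(geno.loci):
            a, b = geno.alleles[k, l]
            rows.append((ind, geno.accession_of[ind], locus,
                         "" if a == MISSING else str(a),
                         "" if b == MISSING else str(b)))
    pd.DataFrame(rows, columns=["individual", "accession", "locus",
                                "allele1", "allele2"]).to_csv(path, index=False)


def _genepop_code(v: int) -> str:
    return "000" if v == MISSING else f"{v:03d}"


def _write_genepop(geno: GenotypeMatrix, path: Path) -> None:
    too_big = geno.alleles[(geno.alleles != MISSING) & (geno.alleles > 999)]
    if too_big.size:
        raise ValueError(
            f"allele size {int(too_big.max())} exceeds 999 for 3-digit "
            "GENEPOP; use write_genepop_recoded to persist a recode map")
    lines = ["beandiv export"]
    lines.extend(geno.loci)
    for acc in geno.accessions:
        lines.append("Pop")
        for k in geno.indices_of(acc):
            codes = " ".join(
                _genepop_code(geno.alleles[k, l, 0])
                + _genepop_code(geno.alleles[k, l, 1])
                for l in range(geno.n_loci))
            lines.append(f"{geno.individuals[k]} , {codes}")
    path.write_text("\n".join(lines) + "\n")


def write_genepop_recoded(geno: GenotypeMatrix, path: str | Path,
                          map_path: str | Path) -> dict:
    """GENEPOP export with >999 bp alleles recoded; map persisted as JSON."""
    path, map_path = Path(path), Path(map_path)
    mapping: dict[str, dict[int, int]] = {}
    recoded = geno.alleles.copy()
    for l, locus in enumerate(geno.loci):
        sizes = sorted({int(v) for v in geno.alleles[:, l].ravel()
                        if v != MISSING})
        code_of = {s: i + 1 for i, s in enumerate(sizes)}
        mapping[locus] = code_of
        for s, c in code_of.items():
            recoded[:, l][geno.alleles[:, l] == s] = c
    _write_genepop(GenotypeMatrix(geno.individuals, geno.loci,
                                  geno.accession_of, recoded), path)
    map_path.write_text(json.dumps(
        {loc: {str(k): v for k, v in m.items()} for loc, m in mapping.items()},
        indent=1))
    return mapping


def _write_structure(geno: GenotypeMatrix, path: Path) -> None:
    accs = geno.accessions
    pop_of = {a: i + 1 for i, a in enumerate(accs)}
    lines = ["\t".join(["id", "pop"] + [f"{loc}.{s}" for loc in geno.loci
                                        for s in (1, 2)])]
    for k, ind in enumerate(geno.individuals):
        vals = []
        for l in range(geno.n_loci):
            for slot in (0, 1):
                v = geno.alleles[k, l, slot]
                vals.append("-9" if v == MISSING else str(int(v)))
        lines.append("\t".join([ind, str(pop_of[geno.accession_of[ind]])]
                               + vals))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Q-matrix files

_QHEADER = re.compile(r"^#\s*(K|lnP)\s*=\s*(\S+)")


def write_q_run(path: str | Path, K: int, lnP: float,
                Q: dict[str, np.ndarray]) -> None:
    lines = [f"# K = {K}", f"# lnP = {lnP}"]
    for ind, q in Q.items():
        lines.append(ind + " " + " ".join(f"{x:.6f}" for x in np.asarray(q)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_q_runs(paths: list[str | Path],
                known_individuals: set[str] | None = None) -> QRunSet:
    """Parse Q-matrix text files (one run each) into a :class:`QRunSet`.

    Each file carries ``# K = ...`` and ``# lnP = ...`` headers followed by
    one ``individual q1 ... qK`` row per individual.  Rows must sum to 1
    within 1e-4; individuals must be in ``known_individuals`` if given.
    """
    qs = QRunSet()
    for path in paths:
        path = Path(path)
        K = lnP = None
        Q: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line:
                continue
            m = _QHEADER.match(line)
            if m:
                if m.group(1) == "K":
                    K = int(m.group(2))
                else:
                    lnP = float(m.group(2))
                continue
            parts = line.split()
            if K is None or lnP is None:
                raise ParseError(f"{path}:{lineno}: data row before K/lnP headers")
            ind, vals = parts[0], parts[1:]
            if len(vals) != K:
                raise ParseError(f"{path}:{lineno}: {len(vals)} memberships "
                                 f"for K={K}")
            q = np.array([float(v) for v in vals])
            if abs(q.sum() - 1.0) > 1e-4 or (q < 0).any():
                raise ParseError(f"{path}:{lineno}: Q row does not sum to 1")
            if known_individuals is not None and ind not in known_individuals:
                raise ParseError(f"{path}:{lineno}: unknown individual {ind!r}")
            Q[ind] = q
        if K is None or lnP is None or not Q:
            raise ParseError(f"{path}: missing K/lnP header or empty run")
        qs.add(path.stem, K, lnP, Q)
    return qs


# ---------------------------------------------------------------------------
# distance-matrix / tree output


def write_phylip_distance(ids: list[str], D: np.ndarray,
                          path: str | Path) -> None:
    """PHYLIP square distance matrix (names truncated/padded to 10 chars)."""
    D = np.asarray(D, dtype=float)
    lines = [f"    {len(ids)}"]
    for i, name in enumerate(ids):
        row = " ".join(f"{D[i, j]:.6f}" for j in range(len(ids)))
        lines.append(f"{name[:10]:<10} {row}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_newick(tree, path: str | Path) -> None:
    """Write a dendropy tree as Newick with internal support labels."""
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True))
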