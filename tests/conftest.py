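import numpy as np
import pytest

from mutstab import DdgMatrix, GeneModel
from mutstab.codon import AA_INDEX, AA_ORDER


def make_matrix(protein_id: str, sequence: str, cells: dict) -> DdgMatrix:
    """Build a matrix from {(1-based position, alt_aa): ddg} with all other
    cells missing."""
    values = np.full((len(sequence), len(AA_ORDER)), np.nan)
    for (pos, alt), ddg in cells.items():
        values[pos - 1, AA_INDEX[alt]] = ddg
    return DdgMatrix(protein_id, sequence, values)


def random_matrix(
    rng: np.random.Generator,
    length: int | None = None,
    sigma: float = 1.0,
    missing_fraction: float = 0.0,
    protein_id: str = "R1",
) -> DdgMatrix:
    """A fully populated random matrix (wild-type cells zero)."""
    L = length or int(rng.integers(3, 30))
    seq = "".join(rng.choice(list(AA_ORDER), size=L))
    values = rng.normal(0.0, sigma, size=(L, len(AA_ORDER)))
    if missing_fraction:
        values[rng.random(values.shape) < missing_fraction] = np.nan
    for i, aa in enumerate(seq):
        values[i, AA_INDEX[aa]] = 0.0
    return DdgMatrix(protein_id, seq, values)


def random_gene(rng: np.random.Generator, n_codons: int = 10,
                gene_id: str = "RG1") -> GeneModel:
    """Random CDS with start, no internal stop, terminal stop, and flanks."""
    from mutstab.simulate import _SENSE_CODONS, _STOP_CODONS

    body = "".join(rng.choice(_SENSE_CODONS, size=n_codons))
    return GeneModel(
        gene_id,
        cds="ATG" + body + str(rng.choice(_STOP_CODONS)),
        upstream_base=str(rng.choice(list("ACGT"))),
        downstream_base=str(rng.choice(list("ACGT"))),
    )


def write_toy_pdb(path, residues):
    """Write a minimal PDB: residues is a list of (resname, [(atom, b)])."""
    lines = []
    serial = 1
    for i, (resname, atoms) in enumerate(residues, start=1):
        for atom, b in atoms:
            element = atom[0]
            lines.append(
                f"ATOM  {serial:5d}  {atom:<3s}{resname:>4s} A{i:4d}    "
                f"{1.0 * serial:8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{b:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


@pytest.fixture
def toy_gene() -> GeneModel:
    # ATG TGG TAA: Met-Trp-stop; TGG is one SNV away from two stops.
    return GeneModel("TOY", cds="ATGTGGTAA", upstream_base="A", downstream_base="C")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
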