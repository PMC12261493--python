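import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mixdta.data import Drug, DTADataset, DTAPair, Protein

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_grid_dataset(n_drugs: int, n_proteins: int, labels=None, density: float = 1.0, seed: int = 0):
    """Fully (or partially) observed drug x protein grid with simple labels."""
    rng = np.random.default_rng(seed)
    drugs = {f"D{i}": Drug(id=f"D{i}", smiles="AB" * (i + 2)) for i in range(n_drugs)}
    proteins = {f"P{j}": Protein(id=f"P{j}", sequence="ACDE" * (j + 2)) for j in range(n_proteins)}
    cells = [(i, j) for i in range(n_drugs) for j in range(n_proteins)]
    if density < 1.0:
        keep = rng.choice(len(cells), size=max(1, int(round(density * len(cells)))), replace=False)
        cells = [cells[k] for k in sorted(keep)]
    pairs = []
    for k, (i, j) in enumerate(cells):
        y = float(labels[k]) if labels is not None else 5.0 + rng.random() * 4.0
        pairs.append(DTAPair(drug_id=f"D{i}", protein_id=f"P{j}", label=y))
    return DTADataset(drugs=drugs, proteins=proteins, pairs=pairs)


@pytest.fixture
def grid3x3():
    return make_grid_dataset(3, 3, labels=np.linspace(5.0, 9.0, 9))
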