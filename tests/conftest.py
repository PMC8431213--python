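import numpy as np
import pandas as pd
import pytest

from fme import synthetic


@pytest.fixture(scope="session")
def compendium():
    """Small seeded compendium with confounders and a 10-gene spike."""
    cfg = synthetic.CompendiumConfig(
        n_genes=120, n_tumor=30, n_normal=30, n_confounders=3,
        confounder_sd=2.0, n_spiked=10, spike_effect=3.0, noise_sd=1.0,
        cna_gain=1.0, seed=11,
    )
    return synthetic.simulate_compendium(cfg)


@pytest.fixture(scope="session")
def biopsy_records():
    """Small 4-group biopsy set (3 per group, 48x48)."""
    groups = {
        "normal": synthetic.BiopsyGroup(3, 1323.0, 589.7, positive_fraction=0.02),
        "LGD": synthetic.BiopsyGroup(3, 2027.0, 1190.0, positive_fraction=0.10),
        "HGD": synthetic.BiopsyGroup(3, 4596.0, 2135.0, positive_fraction=0.30),
        "ESCC": synthetic.BiopsyGroup(3, 4309.0, 2657.0, positive_fraction=0.40),
    }
    cfg = synthetic.BiopsyCohortConfig(
        groups=groups, image_shape=(48, 48), edge_artifact=True, seed=5
    )
    return synthetic.simulate_biopsy_set(cfg)


@pytest.fixture(scope="session")
def rank_table_60():
    """Rank table of 60 upregulated genes, p strictly increasing."""
    gene_ids = [f"G{i:02d}" for i in range(1, 61)]
    return pd.DataFrame(
        {
            "t": np.linspace(12.0, 3.0, 60),
            "df": np.full(60, 50.0),
            "p": np.linspace(1e-6, 1e-3, 60),
            "direction": "up",
            "significant": True,
            "rank": np.arange(1, 61),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


@pytest.fixture(scope="session")
def annotation_60(rank_table_60):
    """Deterministic 60-gene annotation table.

    12 membrane genes, exactly 5 of which satisfy the full selection
    conjunction; flag totals are 12 membrane / 44 carcinogenesis /
    12 esophageal / 20 GI.
    """
    genes = list(rank_table_60.index)
    membrane_idx = [2, 5, 8, 11, 14, 17, 20, 23, 26, 29, 32, 35]
    full_idx = membrane_idx[:5]  # the qualifying candidates
    non_membrane = [i for i in range(60) if i not in membrane_idx]
    carcinogenesis_idx = set(membrane_idx[:12]) | set(non_membrane[:32])
    eso_idx = set(full_idx[:3]) | set(non_membrane[:9])
    gi_idx = set(full_idx) | set(non_membrane[:15])
    rows = []
    for i, g in enumerate(genes):
        rows.append(
            {
                "gene_id": g,
                "membrane": i in membrane_idx,
                "esophageal_overexpression": i in eso_idx,
                # the 7 membrane genes outside full_idx keep carcinogenesis
                # but lack both overexpression flags, so only full_idx pass
                "gi_overexpression": i in gi_idx,
                "carcinogenesis": i in carcinogenesis_idx,
                "localization": "plasma membrane" if i in membrane_idx else "cytoplasm",
            }
        )
    ann = pd.DataFrame(rows).set_index("gene_id")
    expected = [genes[i] for i in full_idx]
    return ann, expected
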