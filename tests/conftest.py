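import numpy as np
import pandas as pd
import pytest

from phosphonet.quant import SiteQuantSummary, classify_regulation, strict_filter


def make_summary(
    mu,
    sigma=0.0,
    n=2,
    site_key="PROT(S10)",
    protein="PROT",
    comparison_id="C1",
    mean_total_intensity=1e6,
    ci_multiplier=1.96,
):
    """Build a summary directly from target statistics (ratios are dummies
    of the right length)."""
    s = SiteQuantSummary(
        site_key=site_key,
        protein_accession=protein,
        comparison_id=comparison_id,
        replicate_log2_ratios=[mu] * n,
        mu=mu,
        sigma=sigma,
        ci_low=mu - ci_multiplier * sigma,
        ci_high=mu + ci_multiplier * sigma,
        mean_total_intensity=mean_total_intensity,
    )
    s.regulation = classify_regulation(s)
    s.strict = strict_filter(s)
    return s


@pytest.fixture
def quant_table_path(tmp_path):
    """Well-formed 10-row quantitation TSV."""
    rng = np.random.default_rng(42)
    rows = []
    for i in range(10):
        rows.append(
            {
                "peptide_id": f"pep{i}",
                "protein": f"P{i % 5}",
                "gene": f"G{i % 5}",
                "sites": "S10" if i % 2 == 0 else "T20/S25",
                "replicate": 1 + i % 2,
                "WT": rng.uniform(1e5, 1e6),
                "WT_FGF": rng.uniform(1e5, 1e6),
                "FUS": rng.uniform(1e5, 1e6),
                "FUS_FGF": rng.uniform(1e5, 1e6),
                "id_fdr": 0.005 if i < 6 else 0.03,
                "total_intensity": 1e6,
            }
        )
    path = tmp_path / "quant.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
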