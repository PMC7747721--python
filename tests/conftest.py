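import pandas as pd
import pytest

from ewaskit import synthetic


def make_manifest(rows: list[tuple]) -> pd.DataFrame:
    """rows: (probe_id, chrom, pos, gene, feature, cgi)."""
    df = pd.DataFrame(
        rows, columns=["probe_id", "chrom", "pos", "gene", "feature", "cgi_relation"]
    ).set_index("probe_id")
    df["on_450k"] = True
    df["on_epic"] = True
    return df


def make_sheet(n_case: int, n_control: int, cohort: str = "discovery") -> pd.DataFrame:
    ids = [f"{cohort}_case_{i}" for i in range(n_case)] + [
        f"{cohort}_ctrl_{i}" for i in range(n_control)
    ]
    return pd.DataFrame(
        {
            "group": ["case"] * n_case + ["control"] * n_control,
            "cohort": cohort,
            "batch": ["s1", "s2"] * ((n_case + n_control) // 2)
            + ["s1"] * ((n_case + n_control) % 2),
        },
        index=pd.Index(ids, name="sample_id"),
    )


@pytest.fixture
def small_cohort():
    """One simulated cohort with a planted 4-CpG hypermethylated region."""
    planted = (synthetic.PlantedDMR("MDGA1", "6", 37_616_410, 4, 500, 0.15, "Body"),)
    design = synthetic.CohortDesign(
        n_case=23, n_control=16, n_probes=300, planted_dmrs=planted, seed=11
    )
    manifest = synthetic.generate_manifest(design)
    beta, sheet = synthetic.generate_cohort(manifest, design)
    return manifest, beta, sheet, design
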