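import numpy as np
import pandas as pd
import pytest

import pgxcohort as pgx


@pytest.fixture(scope="session")
def definitions():
    return pgx.default_definitions()


@pytest.fixture(scope="session")
def small_cohort_run(tmp_path_factory, definitions):
    """A modest simulated cohort shared by read-only tests."""
    out = tmp_path_factory.mktemp("cohort")
    spec = pgx.SimulationSpec(
        n_samples=150, n_background_snps=300, inbreeding=0.05, seed=7
    )
    truth = pgx.simulate_diplotypes(spec, definitions)
    paths = pgx.emit_cohort_vcf(truth, spec, str(out), definitions)
    cm = pgx.CohortMatrix.from_vcf(paths["vcf"])
    return {"spec": spec, "truth": truth, "paths": paths, "cm": cm}


def make_matrix(dosage, samples=None, dp=30.0, gq=60.0, chrom="1"):
    """Handy constructor for small literal cohorts."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    samples = samples or [f"S{i:03d}" for i in range(n)]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * 100,
            "ref": "A",
            "alt": "G",
        }
    )
    dp_arr = np.broadcast_to(np.asarray(dp, dtype=float), (n, m)).copy()
    gq_arr = np.broadcast_to(np.asarray(gq, dtype=float), (n, m)).copy()
    return pgx.CohortMatrix(samples, variants, dosage, dp_arr, gq_arr)


@pytest.fixture
def matrix_factory():
    return make_matrix
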