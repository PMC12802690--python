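"""Shared constructions for the test suite."""

import numpy as np
import pandas as pd

from cortexmeth.io_formats import BetaMatrix


def clustered_dataset(slopes, n_samples=40, noise_sd=0.01, seed=0, gap=80):
    """Sites on one chromosome with consecutive gaps ``gap`` bp and the given
    pp/week slopes; returns (BetaMatrix, sample sheet, annotation)."""
    rng = np.random.default_rng(seed)
    ages = rng.uniform(6, 23, n_samples)
    vals, site_ids, positions = [], [], []
    pos = 1000
    for i, slope in enumerate(slopes):
        mu = 0.4 + slope / 100 * (ages - 6)
        vals.append(np.clip(mu + rng.normal(0, noise_sd, n_samples), 0.001, 0.999))
        site_ids.append(f"cg{i}")
        positions.append(pos)
        pos += gap
    beta = BetaMatrix(site_ids, [f"s{i}" for i in range(n_samples)], np.array(vals))
    sheet = pd.DataFrame(
        {
            "sample_id": beta.sample_ids, "age_value": ages, "age_unit": "pcw",
            "sex": "M", "batch": "b1",
            "donor_id": beta.sample_ids, "fraction": "bulk", "stage": "prenatal",
        }
    )
    annot = pd.DataFrame(
        {
            "site_id": site_ids, "chromosome": "chr1", "position": positions,
            "gene_symbols": [["GENE1"]] * len(site_ids),
        }
    )
    return beta, sheet, annot
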