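"""Shared tiny qPCR designs for the tests."""

from pigmentpattern.synth import QpcrDesign


def two_region_design(offset=0.0, efficiency=2.0, noise=0.0, n=10):
    """One target against two stable references, calibrator BTB vs MTD."""
    offsets = {"rps20": {"BTB": 0.0, "MTD": 0.0},
               "pgk1": {"BTB": 0.0, "MTD": 0.0},
               "tgt": {"BTB": 0.0, "MTD": offset}}
    return QpcrDesign(genes=["rps20", "pgk1", "tgt"], regions=["BTB", "MTD"],
                      offsets=offsets,
                      efficiencies={"rps20": 2.0, "pgk1": 2.0,
                                    "tgt": efficiency},
                      reference_genes=["rps20", "pgk1"], n_individuals=n,
                      noise_sd=noise, individual_sd=0.0 if noise == 0 else 0.3)
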