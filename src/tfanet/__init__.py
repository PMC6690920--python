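"""tfanet: transcription-factor activity network inference.

Three-step pipeline: (1) screen TF–target pairs by Gaussian-kernel mutual
information against a fitted Student-t null; (2) detect modulator–TF–target
triplets by conditional mutual information with permutation significance;
(3) fit a hierarchical linear-Gaussian model with hidden TF activities by
hard-assignment EM (closed-form E-step, sparse ADMM M-step). Downstream:
three-layer network assembly, topology statistics, and context-specific
rewiring analysis. A synthetic-data module provides ground-truth datasets
for every stage.
"""

from .data_io import (
    ExpressionMatrix,
    FunctionalLinkage,
    GeneRoleSets,
    collapse_probes,
    read_expression,
    read_linkage,
    read_pairs,
    read_triplets,
    write_expression,
    write_network,
)
from .mi_inference import (
    MiNullFit,
    RegulatoryPair,
    estimate_bandwidth,
    kernel_mi,
    screen_pairs,
)
from .modulation import (
    ModulationTriplet,
    call_modulators,
    conditional_mi,
    permutation_pvalue,
    split_by_modulator,
)
from .network_analysis import (
    RewiringResult,
    TFANetwork,
    assemble_three_layer,
    degree_summary,
    mi_improvement_test,
    node_betweenness,
    rewiring_analysis,
)
from .synthetic import (
    SyntheticTruth,
    generate_modulated_triplet,
    generate_null_matrix,
    generate_tfa_dataset,
)
from .tfa_model import (
    DEFAULT_LAMBDA,
    DraftNetwork,
    TFAModel,
    admm_lasso,
    e_step,
    fit,
    init_model,
    lasso_lambda_max,
    m_step_dense,
    m_step_sparse,
    penalized_objective,
    select_active_triplets,
    standardize_rows,
    update_variances,
)

__version__ = "0.1.0"

__all__ = [
    "ExpressionMatrix", "FunctionalLinkage", "GeneRoleSets",
    "read_expression", "write_expression", "collapse_probes", "read_linkage",
    "write_network", "read_pairs", "read_triplets",
    "RegulatoryPair", "MiNullFit", "estimate_bandwidth", "kernel_mi",
    "screen_pairs",
    "ModulationTriplet", "split_by_modulator", "conditional_mi",
    "permutation_pvalue", "call_modulators",
    "DraftNetwork", "TFAModel", "init_model", "e_step", "m_step_dense",
    "m_step_sparse", "admm_lasso", "lasso_lambda_max", "update_variances",
    "penalized_objective", "fit", "select_active_triplets",
    "standardize_rows", "DEFAULT_LAMBDA",
    "TFANetwork", "RewiringResult", "assemble_three_layer",
    "node_betweenness", "degree_summary", "mi_improvement_test",
    "rewiring_analysis",
    "SyntheticTruth", "generate_tfa_dataset", "generate_modulated_triplet",
    "generate_null_matrix",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from a global seed (< 2^31)."""
    import zlib

    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)
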