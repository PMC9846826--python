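"""cpqsar: conformal-prediction QSAR screening and prioritization.

Uncertainty-aware bioactivity classification for imbalanced endpoints:
Mondrian inductive conformal prediction wrapped around random-forest
QSAR models, a multi-endpoint screening battery with confidence-tunable
class assignment and out-of-domain flagging, and a prioritization layer
ranking library compounds against reference endocrine disruptors via
conformal-p-value fingerprints and t-SNE clustering.
"""

from .chemistry import (
    AssayDataset,
    CompoundRecord,
    aggregate_replicates,
    compute_descriptors,
    filter_assay,
    read_compound_table,
    standardize_structure,
)
from .conformal import (
    CalibrationTable,
    ConformalResult,
    MondrianICP,
    aggregate_iterations,
    assign_class,
    build_calibration,
    efficiency,
    p_value,
    validity,
)
from .protocols import (
    EndpointModel,
    MetricsReport,
    SplitPlan,
    evaluate,
    resample,
    run_cp_protocol,
    run_protocol_comparison,
    split_stratified,
    train_forest,
)
from .screening import (
    PValueMatrix,
    classify_matrix,
    high_confidence_selection,
    out_of_domain,
    screen,
    summarize,
)
from .prioritization import (
    Embedding2D,
    cluster_around,
    consensus,
    embed,
    fingerprint,
    fingerprint_matrix,
    rank_by_tanimoto,
    tanimoto,
)
from .synthetic import (
    BATTERY_PREVALENCES,
    GeneratorConfig,
    make_battery_fixture,
    make_endpoint_dataset,
    make_replicate_table,
    separation_for_auc,
)

__version__ = "0.1.0"
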