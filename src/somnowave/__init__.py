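"""somnowave: six-class sleep-stage scoring from EEG.

Optimal biorthogonal halfband wavelet filter banks, five-level
sub-band decomposition of 30-s epochs, l1/l2/l-infinity norm features,
class balancing by resampling, and an ensemble of bagged trees
evaluated by repeated stratified 10-fold cross-validation.
"""

from .balancing import STUDY_TARGETS, BalanceSpec, balance_classes
from .ensemble import BaggedTreeModel, fit_bagged, fit_tree, tune
from .evaluation import (
    ConfusionMatrix,
    CVResult,
    aggregate_trials,
    cohens_kappa,
    f1_per_class,
    overall_accuracy,
    per_class_ovr_accuracy,
    repeated_cv,
    roc_ovr,
)
from .features import build_feature_matrix, epoch_features, linf_norm, lm_norm
from .filterbank import (
    HalfbandFilter,
    LinearPhaseFilter,
    WaveletFilterBank,
    design_filter_bank,
    design_halfband_analysis,
    design_synthesis_lowpass,
    make_filter_bank,
    tf_localization,
    vanishing_moments,
    verify_halfband,
)
from .io_epochs import (
    EpochRecord,
    EpochSet,
    epoch_accounting,
    parse_hypnogram,
    read_edf_channel,
    segment_epochs,
    write_edf,
    write_hypnogram,
)
from .pipeline import ExperimentConfig, run_experiment
from .stages import GROUPS, STAGES
from .synthetic import (
    DEFAULT_PROFILES,
    CohortSpec,
    StageProfile,
    generate_cohort,
    generate_epoch,
    healthy_cohort_spec,
)
from .transform import SubbandSet, analyze_one_level, wavedec, waverec
from .anova import anova_oneway, fisher_lsd, rank_features

__version__ = "0.1.0"
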