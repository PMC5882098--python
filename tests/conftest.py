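import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small strong-effect cohort shared by cheap tests (no occult patients)."""
    from hfhisto.synthetic_data import CohortSpec, generate_cohort

    spec = CohortSpec(n_patients=8, prop_failing=0.5, rois_per_patient=3,
                      roi_side_px=192, effect_size="strong", rng_seed=42)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def headline_run():
    """The scaled-down headline experiment: strong-effect 80-patient cohort,
    40 train / 40 test, CNN arm trained end to end.  Shared by the
    operating-point, learnability and rotation-coherence checks."""
    from hfhisto import aggregate_eval as ae
    from hfhisto import cnn
    from hfhisto.pipeline import cnn_image_probabilities, cohort_patchset, score_predictions
    from hfhisto.synthetic_data import CohortSpec, generate_cohort

    seed = 7
    spec = CohortSpec(n_patients=80, prop_failing=0.5, rois_per_patient=11,
                      roi_side_px=320, effect_size="strong", rng_seed=seed)
    cohort = generate_cohort(spec)
    table = cohort.patient_table()
    train_ids, test_ids = ae.train_test_split_patients(table, rng_seed=seed)
    x, y = cohort_patchset(cohort, train_ids, patches_per_roi=6, augment=True, rng_seed=seed)
    model = cnn.build_model(rng_seed=seed)
    model, log = cnn.train(
        model, (x, y), None,
        cnn.TrainingConfig(epochs=3, batch_size=64, learning_rate=0.01, rng_seed=seed),
    )
    labels = {p.patient_id: p.label_v1 for p in cohort.patients}
    preds = cnn_image_probabilities(model, cohort, test_ids)
    scored = score_predictions(preds, labels)
    return {
        "cohort": cohort, "model": model, "log": log, "labels": labels,
        "train_ids": train_ids, "test_ids": test_ids, "preds": preds, "scored": scored,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
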