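# demo run: small synthetic cohort, decision-level fusion on selected features
seed = 0
n_healthy = 60
n_bruised = 60
n_test_healthy = 40
n_test_bruised = 48
classifier = plsda
folds = 10
frog_iters = 90
max_features = 15
level = decision
decision_rule = all
decision_on = features
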