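# Hyperparameter search spaces, one block per learner family.
# Types: int (inclusive), float, logfloat (log-uniform), categorical.
xgboost:
  n_estimators: {type: int, low: 20, high: 600}
  max_depth: {type: int, low: 3, high: 10}
  learning_rate: {type: logfloat, low: 0.01, high: 0.3}
  subsample: {type: float, low: 0.5, high: 1.0}
  colsample_bytree: {type: float, low: 0.5, high: 1.0}
  min_child_weight: {type: int, low: 1, high: 10}
  reg_lambda: {type: logfloat, low: 0.001, high: 10.0}
lightgbm:
  n_estimators: {type: int, low: 20, high: 600}
  num_leaves: {type: int, low: 15, high: 255}
  learning_rate: {type: logfloat, low: 0.01, high: 0.3}
  min_child_samples: {type: int, low: 5, high: 50}
  subsample: {type: float, low: 0.5, high: 1.0}
  colsample_bytree: {type: float, low: 0.5, high: 1.0}
  reg_lambda: {type: logfloat, low: 0.001, high: 10.0}
random_forest:
  n_estimators: {type: int, low: 20, high: 600}
  max_depth: {type: categorical, choices: [null, 5, 10, 20, 40]}
  max_features: {type: categorical, choices: [sqrt, log2, 0.3]}
  min_samples_split: {type: int, low: 2, high: 10}
  min_samples_leaf: {type: int, low: 1, high: 5}
knn:
  n_neighbors: {type: int, low: 1, high: 50}
  weights: {type: categorical, choices: [uniform, distance]}
  p: {type: categorical, choices: [1, 2]}
logistic:
  C: {type: logfloat, low: 0.001, high: 100.0}
  l1_ratio: {type: float, low: 0.0, high: 1.0}
mlp:
  hidden_layer_sizes: {type: categorical, choices: [[64], [128], [64, 32], [128, 64]]}
  alpha: {type: logfloat, low: 0.0001, high: 0.1}
  learning_rate_init: {type: logfloat, low: 0.0005, high: 0.01}
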