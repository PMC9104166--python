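# Hyperparameter search spaces for the nine screening classifiers.
#
# "full" spans the published test ranges of each algorithm; "reduced" is the
# shipped default, a deterministic subset sized for single-CPU grid searches
# on surveys of a few thousand offices. Dimension order and value order are
# significant: grids enumerate as the cross-product in this exact order, and
# ties in a grid search resolve to the earliest point.
full:
  svm_linear:
    C: [0.1, 1, 10, 100, 1000, 10000]
  svm_poly:
    C: [0.1, 1, 10, 100, 1000, 10000]
    degree: [2, 3]
    coef0: [0, 1]
  svm_rbf:
    C: [0.1, 1, 10, 100, 1000, 10000]
  svm_sigmoid:
    C: [0.0001, 0.001, 0.01, 0.1, 1, 10, 100, 2000]
    coef0: [0, 0.25, 0.5, 0.75, 1]
  knn:
    n_neighbors: [2, 3, 4, 5, 6, 7, 8, 9, 10, 11]
    weights: [uniform, distance]
  logistic:
    C: [0.001, 0.01, 0.1, 1, 10, 100, 1000, 20000]
  decision_tree:
    max_depth: [3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14]
    min_samples_split: [3, 5, 7, 9, 11, 13, 15, 17, 19]
    min_samples_leaf: [2, 3, 4, 5, 6]
    criterion: [gini, entropy]
  random_forest:
    n_estimators: [10, 60, 110]
    max_depth: [2, 3, 4, 5, 6, 7, 8, 9, 10, 11]
    min_samples_split: [2, 3, 4, 5, 6, 7, 8, 9]
    min_samples_leaf: [2, 3, 4, 5, 6]
    criterion: [gini, entropy]
  mlp:
    neurons: [100, 200]
    hidden_ratio: [[1], [1, 8, 1], [1, 4, 4, 1], [1, 2, 2, 2, 2, 1]]
    activation: [identity, logistic, tanh, relu]
    solver: [lbfgs, sgd, adam]
    learning_rate: [constant, invscaling, adaptive]
reduced:
  svm_linear:
    C: [0.1, 1, 10, 100]
  svm_poly:
    C: [1, 10]
    degree: [2, 3]
    coef0: [0, 1]
  svm_rbf:
    C: [0.1, 1, 10, 100]
  svm_sigmoid:
    C: [0.0001, 0.01, 1, 100]
    coef0: [0, 0.5]
  knn:
    n_neighbors: [2, 3, 4, 5, 6, 7, 8, 9, 10, 11]
    weights: [uniform, distance]
  logistic:
    C: [0.001, 0.1, 1, 10, 1000, 20000]
  decision_tree:
    max_depth: [3, 7, 10, 14]
    min_samples_split: [3, 9, 19]
    min_samples_leaf: [2, 6]
    criterion: [gini, entropy]
  random_forest:
    n_estimators: [10, 60]
    max_depth: [5, 11]
    min_samples_split: [2, 9]
    min_samples_leaf: [2]
    criterion: [gini, entropy]
  mlp:
    neurons: [100]
    hidden_ratio: [[1]]
    activation: [identity, relu]
    solver: [lbfgs]
    learning_rate: [constant]
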