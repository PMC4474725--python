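subject,BST,LR,RF,SVM,LDA,QDA,MLP
S22,0.56,0.58,0.49,0.48,0.57,0.55,0.56
S23,0.61,0.68,0.55,0.59,0.68,0.53,0.7
S24,0.58,0.58,0.51,0.52,0.58,0.54,0.57
S25,0.31,0.77,0.69,0.6,0.77,0.66,0.73
S26,0.53,0.55,0.53,0.53,0.53,0.5,0.57
S27,0.77,0.83,0.81,0.76,0.8,0.73,0.83
S28,0.54,0.53,0.53,0.51,0.53,0.51,0.52
S29,0.5,0.58,0.51,0.51,0.55,0.52,0.58
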