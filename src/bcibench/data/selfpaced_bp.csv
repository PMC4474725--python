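subject,BST,LR,RF,SVM,LDA,QDA,MLP
S22,0.46,0.64,0.49,0.41,0.64,0.62,0.63
S23,0.54,0.67,0.53,0.5,0.64,0.63,0.66
S24,0.6,0.66,0.58,0.6,0.65,0.64,0.63
S25,0.36,0.78,0.6,0.47,0.79,0.68,0.79
S26,0.59,0.66,0.64,0.56,0.65,0.61,0.66
S27,0.79,0.82,0.78,0.72,0.66,0.72,0.82
S28,0.49,0.51,0.51,0.49,0.5,0.48,0.49
S29,0.52,0.53,0.52,0.53,0.53,0.58,0.53
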