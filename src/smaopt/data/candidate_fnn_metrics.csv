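name,mape,r2
M-1,0.00884,0.99237
M-2,0.00897,0.99340
M-3,0.00949,0.99258
M-4,0.00953,0.99398
M-5,0.00953,0.99326
M-6,0.00964,0.98962
M-7,0.01004,0.99267
M-8,0.01005,0.99191
M-9,0.01016,0.99089
M-10,0.01034,0.99062
M-11,0.01041,0.99005
M-12,0.01044,0.98991
R-1,0.00953,0.99398
R-2,0.00897,0.99340
R-3,0.00953,0.99326
R-4,0.01004,0.99267
R-5,0.01056,0.99263
R-6,0.00949,0.99258
R-7,0.01057,0.99238
R-8,0.00884,0.99237
R-9,0.01109,0.99231
R-10,0.01005,0.99191
R-11,0.01119,0.99146
R-12,0.01045,0.99101
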