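label,mass
smallsp01,19.0139
smallsp02,10.7885
smallsp03,22.6962
smallsp04,23.9902
smallsp05,16.8819
smallsp06,17.3998
smallsp07,19.1237
smallsp08,17.5462
smallsp09,15.9583
smallsp10,23.9917
smallsp11,29.5607
smallsp12,18.8981
smallsp13,25.2712
smallsp14,11.7894
smallsp15,19.8703
largesp01,2716.3686
largesp02,2383.5719
largesp03,2428.1245
largesp04,3420.9755
largesp05,2108.7068
largesp06,1489.3488
largesp07,1331.6862
largesp08,3112.3341
largesp09,4215.3994
largesp10,3113.9871
largesp11,3378.5327
largesp12,2801.9480
largesp13,2342.4338
largesp14,3348.2528
largesp15,2640.1166
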