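>od2_seed_1
YQENRDAMWSLLVRTPIGKAFSMNDWARESVE
>od2_seed_2
YQENKDAMWSLLVRSPIGKAFSMDDWARESVE
>od2_seed_3
YQENRDSMWSLLVRTPVGKAFSMNDWGRESVE
>od2_seed_4
YQENRDALWSLLVRTPIGRAFSMNDWARETVE
>od2_seed_5
YQENRDAMWALLVRTPIGKAYSMNEWARESVE
>od2_seed_6
YQDNRDAMWSLLVKTPIGKAFTMNDWAKESVE
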