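text	is_correct
the shy clerk moves an old coin under the pale moon	1
the tall boy read a small book near the quiet park	0
the old man draws a torn note behind the tall iron gate	1
the wise tutor take a long list after the long noisy trip	0
the tall boy draws a torn note near the quiet park	1
the kind nurse draw an old coin near the quiet park	0
the shy clerk moves a red ball under the pale moon	1
the young girl draw a small book inside the dim hall	0
the young girl keeps a thin rope along the steep road	1
the kind nurse read a small book near the quiet park	0
the young girl moves an old coin by the old stone wall	1
the tall boy take a red ball along the steep road	0
the kind nurse sells a red ball behind the tall iron gate	1
the kind nurse move a long list by the old stone wall	0
the shy clerk moves a torn note along the steep road	1
the bold cook hold an old coin after the long noisy trip	0
the shy clerk takes a thin rope along the steep road	1
the kind nurse find a torn note behind the tall iron gate	0
the young girl sells an old coin along the steep road	1
the calm pilot take a blue cup along the steep road	0
the calm pilot takes an old coin along the steep road	1
the shy clerk find a blue cup behind the tall iron gate	0
the tall boy holds a torn note by the old stone wall	1
the young girl read a thin rope after the long noisy trip	0
the kind nurse draws a blue cup under the pale moon	1
the shy clerk sell a small book near the quiet park	0
the calm pilot keeps an old coin under the pale moon	1
the shy clerk find a long list after the long noisy trip	0
the calm pilot holds a red ball near the quiet park	1
the wise tutor find a long list under the pale moon	0
the bold cook reads an old coin by the old stone wall	1
the bold cook keep a long list by the old stone wall	0
the bold cook holds a red ball behind the tall iron gate	1
the young girl keep a torn note near the quiet park	0
the wise tutor moves a red ball behind the tall iron gate	1
the kind nurse find a thin rope behind the tall iron gate	0
the old man finds a small book along the steep road	1
the bold cook take a blue cup behind the tall iron gate	0
the wise tutor sells a small book inside the dim hall	1
the shy clerk draw a thin rope inside the dim hall	0
the kind nurse takes a worn map after the long noisy trip	1
the young girl find a blue cup after the long noisy trip	0
the old man reads a worn map after the long noisy trip	1
the bold cook sell a torn note behind the tall iron gate	0
the young girl sells a red ball behind the tall iron gate	1
the tall boy hold an old coin behind the tall iron gate	0
the tall boy sells a thin rope after the long noisy trip	1
the old man find a blue cup under the pale moon	0
the bold cook draws a worn map behind the tall iron gate	1
the bold cook keep a thin rope inside the dim hall	0
the calm pilot finds a worn map behind the tall iron gate	1
the calm pilot read a red ball after the long noisy trip	0
the old man takes an old coin near the quiet park	1
the bold cook move a blue cup near the quiet park	0
the young girl draws a worn map inside the dim hall	1
the bold cook sell a blue cup near the quiet park	0
the kind nurse draws an old coin near the quiet park	1
the calm pilot keep a worn map inside the dim hall	0
the shy clerk sells a worn map inside the dim hall	1
the shy clerk keep a blue cup under the pale moon	0
the old man sells a worn map under the pale moon	1
the old man read a red ball along the steep road	0
the shy clerk takes a red ball inside the dim hall	1
the shy clerk draw a small book inside the dim hall	0
the kind nurse keeps a thin rope along the steep road	1
the kind nurse draw a red ball by the old stone wall	0
the calm pilot sells a torn note along the steep road	1
the young girl take a worn map by the old stone wall	0
the young girl draws a long list under the pale moon	1
the shy clerk find a small book behind the tall iron gate	0
the bold cook reads an old coin after the long noisy trip	1
the shy clerk find a red ball after the long noisy trip	0
the young girl reads a small book along the steep road	1
the young girl read a blue cup by the old stone wall	0
the wise tutor keeps a long list by the old stone wall	1
the calm pilot sell a red ball near the quiet park	0
the young girl draws a thin rope near the quiet park	1
the kind nurse find a thin rope inside the dim hall	0
the tall boy finds a thin rope behind the tall iron gate	1
the calm pilot draw a small book along the steep road	0
the bold cook keeps an old coin behind the tall iron gate	1
the calm pilot sell a worn map inside the dim hall	0
the calm pilot keeps a small book under the pale moon	1
the tall boy sell a blue cup after the long noisy trip	0
the tall boy moves an old coin behind the tall iron gate	1
the wise tutor sell a long list after the long noisy trip	0
the calm pilot draws a long list under the pale moon	1
the wise tutor hold a small book by the old stone wall	0
the young girl moves a red ball under the pale moon	1
the calm pilot find a long list behind the tall iron gate	0
the wise tutor takes a torn note by the old stone wall	1
the calm pilot hold a red ball inside the dim hall	0
the shy clerk takes a blue cup near the quiet park	1
the wise tutor sell a small book inside the dim hall	0
the calm pilot sells an old coin by the old stone wall	1
the bold cook keep a red ball under the pale moon	0
the tall boy moves an old coin under the pale moon	1
the calm pilot take a long list by the old stone wall	0
the bold cook sells a small book near the quiet park	1
the wise tutor find an old coin after the long noisy trip	0
the tall boy holds a torn note along the steep road	1
the bold cook read a torn note after the long noisy trip	0
the tall boy reads a blue cup along the steep road	1
the bold cook draw a worn map inside the dim hall	0
the wise tutor sells a worn map after the long noisy trip	1
the wise tutor read a worn map near the quiet park	0
the old man draws a torn note by the old stone wall	1
the bold cook find a small book under the pale moon	0
the tall boy moves a blue cup along the steep road	1
the young girl move a small book inside the dim hall	0
the old man reads a small book by the old stone wall	1
the tall boy hold a torn note after the long noisy trip	0
the bold cook finds an old coin behind the tall iron gate	1
the wise tutor hold a blue cup behind the tall iron gate	0
the young girl draws a torn note inside the dim hall	1
the shy clerk draw a thin rope by the old stone wall	0
the shy clerk moves a thin rope behind the tall iron gate	1
the bold cook read an old coin after the long noisy trip	0
the young girl finds an old coin along the steep road	1
the calm pilot sell a blue cup after the long noisy trip	0
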